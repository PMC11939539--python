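"""Ridge-width measurement from grey-value line profiles.

At each grid position a wide-line grey-value profile is sampled across the
ridge.  The two bright cortical plates bounding the ridge appear as the
outermost local maxima of the profile; the alveolar crest width at that
position is the difference of their x-coordinates (mm).  Peaks are filtered by
topographic prominence to suppress noise, and quality-control flags mark
profiles that need review (extra maxima, maxima touching the profile ends,
unmeasurable positions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks

from .errors import GeometryError, MeasurementError, ParameterError
from .grid import MeasurementGrid, MeasurementLine, PositionLabel
from .volume_io import VolumeStack

__all__ = [
    "GreyProfile",
    "PeakSet",
    "WidthMeasurement",
    "extract_profile",
    "find_profile_peaks",
    "ridge_width",
    "measure_grid",
    "measurements_to_frame",
]

DEFAULT_PROMINENCE_FRACTION = 0.1

# QC flags
EXTRA_PEAKS = "EXTRA_PEAKS"
BOUNDARY_PEAK = "BOUNDARY_PEAK"
FLAT_PROFILE = "FLAT_PROFILE"
UNMEASURABLE = "UNMEASURABLE"


@dataclass(frozen=True)
class GreyProfile:
    """Mean grey value vs. distance (mm) along one measurement line."""

    distance_mm: np.ndarray
    value: np.ndarray
    line: MeasurementLine

    @property
    def pitch_mm(self) -> float:
        return float(self.distance_mm[1] - self.distance_mm[0])

    @property
    def span_mm(self) -> tuple[float, float]:
        return float(self.distance_mm[0]), float(self.distance_mm[-1])


@dataclass(frozen=True)
class PeakSet:
    """Local maxima/minima of a profile above a prominence threshold."""

    maxima: tuple[tuple[float, float], ...]  # (x_mm, grey value), x increasing
    minima: tuple[tuple[float, float], ...]
    prominence_threshold: float
    span_mm: tuple[float, float]
    pitch_mm: float
    flat: bool = False


@dataclass(frozen=True)
class WidthMeasurement:
    """Per-position ridge width with the peak pair that produced it.

    ``width_mm`` is None for an explicitly unmeasurable position (fewer than
    two maxima); such positions are reported, never silently dropped.
    """

    label: PositionLabel
    width_mm: float | None
    peak_left_mm: float | None = None
    peak_right_mm: float | None = None
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def measurable(self) -> bool:
        return self.width_mm is not None


def extract_profile(stack: VolumeStack, line: MeasurementLine) -> GreyProfile:
    """Sample the wide-line grey-value profile for one measurement line.

    Samples are taken at steps equal to the in-plane voxel pitch along the
    line.  Each sample is the arithmetic mean of ``sampling_width_px``
    bilinear samples spaced one pixel apart along the perpendicular, centred
    on the line — the behaviour of a plot profile over a wide line selection.
    """
    if not (0 <= line.slice_index < stack.depth):
        raise GeometryError(f"slice index {line.slice_index} outside depth {stack.depth}")
    pitch = stack.in_plane_pitch
    length = line.length_mm
    n = int(math.floor(length / pitch + 1e-9)) + 1
    if n < 2:
        raise GeometryError(f"line of length {length:.3f} mm shorter than one pitch {pitch} mm")

    distances = np.arange(n) * pitch
    dx, dy = line.direction
    nx, ny = line.normal
    w = line.sampling_width_px
    lateral = (np.arange(w) - (w - 1) / 2.0) * pitch

    # sample coordinates (mm): n along the line x w across it
    xs = line.p_start[0] + np.outer(distances, dx) + np.outer(np.ones(n), lateral * nx)
    ys = line.p_start[1] + np.outer(distances, dy) + np.outer(np.ones(n), lateral * ny)

    _, dy_mm, dx_mm = stack.voxel_size
    rows = ys / dy_mm
    cols = xs / dx_mm
    _, nrows, ncols = stack.shape
    eps = 1e-6
    if (
        rows.min() < -eps
        or cols.min() < -eps
        or rows.max() > nrows - 1 + eps
        or cols.max() > ncols - 1 + eps
    ):
        raise GeometryError(
            f"sampling band of line {line.label} exits the volume "
            f"(rows {rows.min():.2f}..{rows.max():.2f} of {nrows}, "
            f"cols {cols.min():.2f}..{cols.max():.2f} of {ncols})"
        )

    plane = stack.voxels[line.slice_index].astype(np.float64)
    samples = ndimage.map_coordinates(
        plane, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
    ).reshape(n, w)
    return GreyProfile(distance_mm=distances, value=samples.mean(axis=1), line=line)


def find_profile_peaks(
    profile: GreyProfile,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> PeakSet:
    """Local maxima and minima with topographic prominence at least
    ``prominence_fraction`` of the profile's dynamic range.

    Plateaus report their centre sample (the lower-index one for even-length
    plateaus).  A flat profile yields empty peak sets flagged ``flat``.
    """
    if not (0 < prominence_fraction < 1):
        raise ParameterError(f"prominence_fraction must be in (0, 1), got {prominence_fraction}")
    v = np.asarray(profile.value, dtype=np.float64)
    if v.size < 3:
        raise ParameterError("profile needs at least 3 samples for peak detection")
    rng = float(v.max() - v.min())
    span = profile.span_mm
    if rng == 0.0:
        return PeakSet((), (), 0.0, span, profile.pitch_mm, flat=True)
    threshold = prominence_fraction * rng
    imax, _ = find_peaks(v, prominence=threshold)
    imin, _ = find_peaks(-v, prominence=threshold)
    x = profile.distance_mm
    return PeakSet(
        maxima=tuple((float(x[i]), float(v[i])) for i in imax),
        minima=tuple((float(x[i]), float(v[i])) for i in imin),
        prominence_threshold=threshold,
        span_mm=span,
        pitch_mm=profile.pitch_mm,
    )


def ridge_width(peaks: PeakSet, label: PositionLabel | None = None) -> WidthMeasurement:
    """Ridge width from the two *outermost* maxima (the cortical rims).

    More than two maxima sets ``EXTRA_PEAKS`` for review — the outer pair
    still bounds the ridge anatomically.  An outer maximum within one sampling
    step of the profile boundary sets ``BOUNDARY_PEAK``: the line may not
    extend beyond the ridge width there.
    """
    if label is None:
        label = PositionLabel(0.0)
    if len(peaks.maxima) < 2:
        raise MeasurementError(
            f"position {label}: {len(peaks.maxima)} maxima found, need 2 to bound the ridge"
        )
    left_x = peaks.maxima[0][0]
    right_x = peaks.maxima[-1][0]
    flags = set()
    if len(peaks.maxima) > 2:
        flags.add(EXTRA_PEAKS)
    lo, hi = peaks.span_mm
    step = peaks.pitch_mm + 1e-9
    if left_x - lo <= step or hi - right_x <= step:
        flags.add(BOUNDARY_PEAK)
    return WidthMeasurement(
        label=label,
        width_mm=right_x - left_x,
        peak_left_mm=left_x,
        peak_right_mm=right_x,
        qc_flags=frozenset(flags),
    )


def measure_grid(
    stack: VolumeStack,
    grid: MeasurementGrid,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> list[WidthMeasurement]:
    """Measure every grid position; one record per position, in label order.

    Positions where fewer than two maxima survive the prominence filter are
    returned as explicit unmeasurable records (``width_mm is None``) rather
    than raised, so a single flat profile does not abort a 15-position run.
    """
    results: list[WidthMeasurement] = []
    for line in sorted(grid, key=lambda ln: (ln.label.depth_mm, ln.label.offset_mm)):
        profile = extract_profile(stack, line)
        peaks = find_profile_peaks(profile, prominence_fraction)
        flags = {FLAT_PROFILE} if peaks.flat else set()
        try:
            m = ridge_width(peaks, line.label)
            if flags:
                m = WidthMeasurement(
                    m.label, m.width_mm, m.peak_left_mm, m.peak_right_mm,
                    frozenset(m.qc_flags | flags),
                )
            results.append(m)
        except MeasurementError:
            results.append(
                WidthMeasurement(
                    label=line.label,
                    width_mm=None,
                    qc_flags=frozenset(flags | {UNMEASURABLE}),
                )
            )
    return results


def measurements_to_frame(
    measurements: Sequence[WidthMeasurement],
    scan_id: str = "",
    timepoint: str = "",
) -> pd.DataFrame:
    """Tabulate measurements: one row per grid position."""
    rows = [
        {
            "scan_id": scan_id,
            "timepoint": timepoint,
            "offset_mm": m.label.offset_mm,
            "depth_level": m.label.depth_name,
            "depth_mm": m.label.depth_mm,
            "width_mm": np.nan if m.width_mm is None else m.width_mm,
            "peak_left_mm": np.nan if m.peak_left_mm is None else m.peak_left_mm,
            "peak_right_mm": np.nan if m.peak_right_mm is None else m.peak_right_mm,
            "flags": "|".join(sorted(m.qc_flags)),
        }
        for m in measurements
    ]
    return pd.DataFrame(rows)
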