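"""Synthetic CBCT phantom of an alveolar ridge with known ground truth.

The phantom renders, slice by slice, a ridge cross-section: two bright
cortical rim bands separated by a position-specific true width, trabecular
fill between them, and a low-intensity socket channel at the central
positions.  The follow-up volume renders the same geometry minus a programmed
per-position width loss whose default pattern is crestally and centrally
weighted (greatest loss at the central-crestal position, tapering laterally
and apically) — the qualitative resorption pattern seen clinically after
unassisted socket healing.  Partial-volume averaging, a Gaussian point-spread
blur and additive Gaussian noise emulate the imaging chain.

Design notes
------------
* Geometry is modelled as parallel rim bands per slice, not full anatomy: the
  measurement method reads one wide-line profile per position, so fidelity
  beyond rim placement adds nothing testable.
* Default rim centres fall exactly on voxel centres (widths and losses are
  multiples of twice the voxel pitch), so the noiseless phantom has an exact
  expected peak sample and measurement error isolates pipeline defects rather
  than grid quantization.
* True widths and losses are piecewise-constant laterally in 1 mm bins
  centred on the measurement offsets and axially in zones around the three
  measurement planes, so each position has a single unambiguous truth value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import PhantomSpecError
from .grid import (
    MeasurementGrid,
    MeasurementLine,
    build_grid,
    make_central_line,
    select_depth_slices,
)
from .volume_io import VolumeStack, round_half_up, write_dicom_series

__all__ = ["PhantomSpec", "generate_phantom", "default_central_line", "default_grid", "write_fixture"]

_OFFSETS_MM = (-2.0, -1.0, 0.0, 1.0, 2.0)
_DEPTH_TARGETS_MM = (2.5, 5.0)

# Default true widths (mm) per depth zone (crestal, -2.5, -5.0), constant
# across offsets: the ridge flares slightly toward apical.
_DEFAULT_WIDTHS = (
    (7.2, 7.2, 7.2, 7.2, 7.2),
    (7.8, 7.8, 7.8, 7.8, 7.8),
    (8.4, 8.4, 8.4, 8.4, 8.4),
)
# Default programmed loss (mm) per (depth zone, offset): maximal at the
# central-crestal position, tapering mesially/distally and apically.
_DEFAULT_LOSS = (
    (1.5, 1.8, 2.1, 1.8, 1.5),
    (0.6, 0.9, 1.2, 0.9, 0.6),
    (0.0, 0.3, 0.6, 0.3, 0.0),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one baseline/follow-up phantom pair.

    All randomness (the additive noise) flows from ``seed``; the geometry and
    therefore the ground-truth table are seed-independent.
    """

    shape: tuple[int, int, int] = (45, 60, 90)  # slices, rows, cols
    voxel_size: tuple[float, float, float] = (0.15, 0.15, 0.15)
    crestal_slice: int = 5
    widths_mm: tuple[tuple[float, ...], ...] = _DEFAULT_WIDTHS  # (3 zones x 5 offsets)
    loss_mm: tuple[tuple[float, ...], ...] = _DEFAULT_LOSS
    zone_boundaries_mm: tuple[float, float] = (1.25, 3.75)  # apical depth cuts between zones
    rim_thickness_mm: float = 0.6
    socket_width_mm: float = 2.0
    rim_intensity: float = 220.0
    trabecular_intensity: float = 100.0
    socket_intensity: float = 60.0
    background_intensity: float = 40.0
    psf_sigma_mm: float = 0.15
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "widths_mm", tuple(tuple(map(float, r)) for r in self.widths_mm))
        object.__setattr__(self, "loss_mm", tuple(tuple(map(float, r)) for r in self.loss_mm))
        object.__setattr__(self, "zone_boundaries_mm", tuple(float(v) for v in self.zone_boundaries_mm))
        w = np.asarray(self.widths_mm, dtype=np.float64)
        l = np.asarray(self.loss_mm, dtype=np.float64)
        if w.shape != (3, 5) or l.shape != (3, 5):
            raise PhantomSpecError("widths_mm and loss_mm must be 3 depth zones x 5 offsets")
        if np.any(w - l <= 0):
            raise PhantomSpecError("programmed loss must stay below the baseline width everywhere")
        if np.any(w <= 0):
            raise PhantomSpecError("true widths must be positive")
        ints = (
            self.rim_intensity,
            self.trabecular_intensity,
            self.socket_intensity,
            self.background_intensity,
        )
        if any(not (0 <= v <= 255) for v in ints):
            raise PhantomSpecError(f"intensities must lie in [0, 255], got {ints}")
        if not (
            self.rim_intensity > self.trabecular_intensity > self.socket_intensity >= self.background_intensity
        ):
            raise PhantomSpecError("need rim > trabecular > socket >= background intensity")
        if self.noise_sd < 0 or self.psf_sigma_mm < 0:
            raise PhantomSpecError("noise_sd and psf_sigma_mm must be non-negative")
        # the ridge (widest zone + rims) must fit inside the rendered plane
        half_extent = float(w.max()) / 2.0 + self.rim_thickness_mm
        x_max = (self.shape[2] - 1) * self.voxel_size[2]
        if self.ridge_center_x_mm - half_extent < 0 or self.ridge_center_x_mm + half_extent > x_max:
            raise PhantomSpecError(
                f"ridge (half extent {half_extent:g} mm) exceeds the plane width {x_max:g} mm"
            )
        if not (0 <= self.crestal_slice < self.shape[0]):
            raise PhantomSpecError("crestal_slice outside the volume")

    # -- geometry helpers ---------------------------------------------------
    @property
    def ridge_center_x_mm(self) -> float:
        cols = self.shape[2]
        return ((cols - 1) // 2) * self.voxel_size[2]  # on a voxel centre

    @property
    def socket_center_y_mm(self) -> float:
        rows = self.shape[1]
        return ((rows - 1) // 2) * self.voxel_size[1]

    def offset_bin(self, y_mm: float) -> int:
        """Lateral 1 mm bin index (0..4) for a row coordinate."""
        rel = y_mm - self.socket_center_y_mm
        return int(np.clip(round(rel), -2, 2)) + 2

    def depth_zone(self, slice_index: int) -> int:
        depth = (slice_index - self.crestal_slice) * self.voxel_size[0]
        if depth < self.zone_boundaries_mm[0]:
            return 0
        if depth < self.zone_boundaries_mm[1]:
            return 1
        return 2

    def true_width(self, offset_mm: float, slice_index: int, timepoint: str) -> float:
        zone = self.depth_zone(slice_index)
        idx = self.offset_bin(self.socket_center_y_mm + offset_mm)
        w = self.widths_mm[zone][idx]
        if timepoint == "t1":
            w -= self.loss_mm[zone][idx]
        return float(w)

    def to_dict(self) -> dict:
        return asdict(self)


def _box_average_profile(breaks: np.ndarray, values: np.ndarray, centers: np.ndarray, pitch: float) -> np.ndarray:
    """Average a piecewise-constant function over voxel extents (partial
    volume along the profile axis).

    ``breaks`` are the region boundaries (len = len(values) + 1, increasing),
    ``values`` the constant value of each region, ``centers`` the voxel
    centre coordinates.
    """
    # integral F(x) of the piecewise-constant function
    seg = np.diff(breaks) * values
    cum = np.concatenate([[0.0], np.cumsum(seg)])

    def F(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, breaks[0], breaks[-1])
        idx = np.clip(np.searchsorted(breaks, x, side="right") - 1, 0, len(values) - 1)
        return cum[idx] + (x - breaks[idx]) * values[idx]

    lo = centers - pitch / 2.0
    hi = centers + pitch / 2.0
    return (F(hi) - F(lo)) / pitch


def _render(spec: PhantomSpec, timepoint: str, rng: np.random.Generator) -> np.ndarray:
    slices, rows, cols = spec.shape
    dz, dy, dx = spec.voxel_size
    xc = spec.ridge_center_x_mm
    centers = np.arange(cols) * dx

    # only 3 zones x 5 bins distinct rows exist; render each once
    profiles: dict[tuple[int, int], np.ndarray] = {}
    for zone in range(3):
        for idx in range(5):
            w = spec.widths_mm[zone][idx]
            if timepoint == "t1":
                w -= spec.loss_mm[zone][idx]
            half = w / 2.0
            t = spec.rim_thickness_mm
            inner = spec.socket_intensity if idx == 2 else spec.trabecular_intensity
            sw = min(spec.socket_width_mm, max(w - 2 * t, 0.0))
            # regions along x: bg | rim | trabecular | (socket) | trabecular | rim | bg
            breaks = [
                -np.inf,
                xc - half - t / 2.0,
                xc - half + t / 2.0,
                xc - sw / 2.0,
                xc + sw / 2.0,
                xc + half - t / 2.0,
                xc + half + t / 2.0,
                np.inf,
            ]
            values = [
                spec.background_intensity,
                spec.rim_intensity,
                spec.trabecular_intensity,
                inner,
                spec.trabecular_intensity,
                spec.rim_intensity,
                spec.background_intensity,
            ]
            b = np.array(breaks)
            b[0] = centers[0] - dx
            b[-1] = centers[-1] + dx
            profiles[(zone, idx)] = _box_average_profile(b, np.array(values), centers, dx)

    # Partial volume along y: each row averages the lateral-bin profiles by
    # overlap of its extent with the 1 mm bins (outer bins extend to the
    # volume edge), so bin boundaries that coincide with a row grid line are
    # split symmetrically instead of flipping on floating-point noise.
    yc = spec.socket_center_y_mm
    bin_edges = yc + np.array([-np.inf, -1.5, -0.5, 0.5, 1.5, np.inf])
    row_weights = np.zeros((rows, 5))
    for r in range(rows):
        lo, hi = r * dy - dy / 2.0, r * dy + dy / 2.0
        for b in range(5):
            overlap = min(hi, bin_edges[b + 1]) - max(lo, bin_edges[b])
            row_weights[r, b] = max(overlap, 0.0) / dy

    vol = np.empty((slices, rows, cols), dtype=np.float64)
    zone_rows = {
        zone: row_weights @ np.stack([profiles[(zone, idx)] for idx in range(5)])
        for zone in range(3)
    }
    for z in range(slices):
        vol[z] = zone_rows[spec.depth_zone(z)]

    if spec.psf_sigma_mm > 0:
        sigma_vox = (spec.psf_sigma_mm / dz, spec.psf_sigma_mm / dy, spec.psf_sigma_mm / dx)
        vol = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    return np.clip(round_half_up(vol), 0, 255).astype(np.uint8)


def default_central_line(spec: PhantomSpec) -> MeasurementLine:
    """The pre-positioned central crestal line for this phantom: through the
    socket centre, perpendicular to the ridge, extending beyond it, with
    endpoints on voxel centres."""
    dy, dx = spec.voxel_size[1], spec.voxel_size[2]
    y = spec.socket_center_y_mm
    cols = spec.shape[2]
    return make_central_line(
        crestal_slice=spec.crestal_slice,
        p_start=(5 * dx, y),
        p_end=((cols - 6) * dx, y),
        bounds_mm=((cols - 1) * dx, (spec.shape[1] - 1) * dy),
    )


def default_grid(spec: PhantomSpec) -> MeasurementGrid:
    """The default 15-position grid for this phantom."""
    central = default_central_line(spec)
    depth_slices = select_depth_slices(
        spec.crestal_slice, spec.voxel_size[0], _DEPTH_TARGETS_MM, depth=spec.shape[0]
    )
    return build_grid(
        central,
        depth_slices,
        bounds_mm=((spec.shape[2] - 1) * spec.voxel_size[2], (spec.shape[1] - 1) * spec.voxel_size[1]),
    )


def _truth_table(spec: PhantomSpec) -> pd.DataFrame:
    depth_slices = select_depth_slices(
        spec.crestal_slice, spec.voxel_size[0], _DEPTH_TARGETS_MM, depth=spec.shape[0]
    )
    planes = [("crestal", 0.0, spec.crestal_slice)] + [
        (f"-{t:g}", t, s) for t, s in zip(_DEPTH_TARGETS_MM, depth_slices)
    ]
    rows = []
    for timepoint in ("t0", "t1"):
        for depth_name, depth_mm, slice_index in planes:
            for offset in _OFFSETS_MM:
                rows.append(
                    {
                        "timepoint": timepoint,
                        "offset_mm": offset,
                        "depth_level": depth_name,
                        "depth_mm": depth_mm,
                        "slice_index": slice_index,
                        "true_width_mm": spec.true_width(offset, slice_index, timepoint),
                    }
                )
    return pd.DataFrame(rows)


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeStack, VolumeStack, pd.DataFrame]:
    """Render the baseline (t0) and follow-up (t1) volumes plus ground truth.

    The same seed always reproduces bit-identical volumes; the ground-truth
    table depends only on the geometry, never on the seed.
    """
    rng = np.random.default_rng(spec.seed)
    t0 = _render(spec, "t0", rng)
    t1 = _render(spec, "t1", rng)
    meta = dict(voxel_size=spec.voxel_size, bit_depth=8)
    stack0 = VolumeStack(voxels=t0, provenance=[f"phantom[t0, seed={spec.seed}]"], **meta)
    stack1 = VolumeStack(voxels=t1, provenance=[f"phantom[t1, seed={spec.seed}]"], **meta)
    return stack0, stack1, _truth_table(spec)


def write_fixture(spec: PhantomSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic fixture: two DICOM series, the ground-truth
    table, a pre-positioned central line and a manifest with spec + seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack0, stack1, truth = generate_phantom(spec)

    paths = {
        "t0": out / "t0",
        "t1": out / "t1",
        "truth": out / "truth.csv",
        "central_line": out / "central_line.json",
        "manifest": out / "manifest.yaml",
    }
    write_dicom_series(stack0, paths["t0"], series_description="phantom t0",
                       uid_entropy=f"ridgewidth-phantom-{spec.seed}-t0")
    write_dicom_series(stack1, paths["t1"], series_description="phantom t1",
                       uid_entropy=f"ridgewidth-phantom-{spec.seed}-t1")
    truth.to_csv(paths["truth"], index=False)

    central = default_central_line(spec)
    paths["central_line"].write_text(json.dumps(central.to_dict(), indent=1))
    manifest = {"generator": "ridgewidth.phantom", "spec": spec.to_dict()}
    paths["manifest"].write_text(yaml.safe_dump(manifest))
    return paths
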