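"""The 15-position measurement grid.

One user-drawn line — perpendicular to the alveolar ridge at the centre of the
socket on the crestal slice — is expanded into 5 horizontal positions (the
central line plus copies shifted 1 mm and 2 mm mesially and distally along the
in-plane perpendicular) on each of 3 depth planes (crestal, 2.5 mm and 5.0 mm
apical, each within a +/-0.25 mm tolerance), for 15 positions in total.

In-plane points are (x, y) millimetre pairs; see :mod:`ridgewidth.volume_io`
for the coordinate conventions.  The sign convention for horizontal offsets is
positive = distal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import BoundsError, GeometryError, ParameterError, ToleranceError

__all__ = [
    "CRESTAL",
    "PositionLabel",
    "MeasurementLine",
    "MeasurementGrid",
    "make_central_line",
    "expand_horizontal",
    "select_depth_slices",
    "build_grid",
]

CRESTAL = 0.0  # depth_mm of the crestal plane

DEFAULT_OFFSETS_MM = (-2.0, -1.0, 1.0, 2.0)
DEFAULT_DEPTH_TARGETS_MM = (2.5, 5.0)
DEFAULT_DEPTH_TOLERANCE_MM = 0.25
DEFAULT_SAMPLING_WIDTH_PX = 10  # wide-line profile: average over >= 10 pixels


@dataclass(frozen=True)
class PositionLabel:
    """Grid position: horizontal offset (mm, + = distal) x depth plane
    (mm apical to the crest; 0.0 = crestal)."""

    offset_mm: float
    depth_mm: float = CRESTAL

    @property
    def depth_name(self) -> str:
        return "crestal" if self.depth_mm == CRESTAL else f"-{self.depth_mm:g}"

    def __str__(self) -> str:
        return f"({self.offset_mm:+g} mm, {self.depth_name})"


@dataclass(frozen=True)
class MeasurementLine:
    """One oriented in-plane measurement segment.

    ``p_start`` -> ``p_end`` defines the vestibular -> oral axis; distances
    along the grey-value profile are reported from ``p_start``.  The profile
    is averaged over ``sampling_width_px`` parallel sample rows spaced one
    pixel apart, centred on the line.
    """

    slice_index: int
    p_start: tuple[float, float]
    p_end: tuple[float, float]
    sampling_width_px: int = DEFAULT_SAMPLING_WIDTH_PX
    label: PositionLabel = PositionLabel(0.0, CRESTAL)

    def __post_init__(self) -> None:
        if self.sampling_width_px < 1:
            raise ParameterError(f"sampling_width_px must be >= 1, got {self.sampling_width_px}")
        if self.length_mm <= 0.0:
            raise GeometryError("zero-length measurement line (p_start == p_end)")

    @property
    def length_mm(self) -> float:
        return math.hypot(self.p_end[0] - self.p_start[0], self.p_end[1] - self.p_start[1])

    @property
    def direction(self) -> tuple[float, float]:
        """Unit vector along the line (vestibular -> oral)."""
        length = self.length_mm
        return (
            (self.p_end[0] - self.p_start[0]) / length,
            (self.p_end[1] - self.p_start[1]) / length,
        )

    @property
    def normal(self) -> tuple[float, float]:
        """Unit vector perpendicular to the line (the mesio-distal axis);
        offsets along +normal are distal by convention."""
        dx, dy = self.direction
        return (-dy, dx)

    def shifted(self, offset_mm: float) -> "MeasurementLine":
        nx, ny = self.normal
        return replace(
            self,
            p_start=(self.p_start[0] + offset_mm * nx, self.p_start[1] + offset_mm * ny),
            p_end=(self.p_end[0] + offset_mm * nx, self.p_end[1] + offset_mm * ny),
            label=PositionLabel(self.label.offset_mm + offset_mm, self.label.depth_mm),
        )

    def on_slice(self, slice_index: int, depth_mm: float) -> "MeasurementLine":
        """Copy with identical in-plane endpoints on another axial slice."""
        return replace(
            self,
            slice_index=slice_index,
            label=PositionLabel(self.label.offset_mm, depth_mm),
        )

    def to_dict(self) -> dict:
        return {
            "slice_index": self.slice_index,
            "p_start": list(self.p_start),
            "p_end": list(self.p_end),
            "sampling_width_px": self.sampling_width_px,
            "offset_mm": self.label.offset_mm,
            "depth_mm": self.label.depth_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementLine":
        return cls(
            slice_index=int(d["slice_index"]),
            p_start=tuple(d["p_start"]),
            p_end=tuple(d["p_end"]),
            sampling_width_px=int(d.get("sampling_width_px", DEFAULT_SAMPLING_WIDTH_PX)),
            label=PositionLabel(float(d.get("offset_mm", 0.0)), float(d.get("depth_mm", CRESTAL))),
        )


def _check_bounds(line: MeasurementLine, bounds_mm: tuple[float, float] | None, what: str) -> None:
    if bounds_mm is None:
        return
    bx, by = bounds_mm
    for px, py in (line.p_start, line.p_end):
        if not (-1e-9 <= px <= bx + 1e-9 and -1e-9 <= py <= by + 1e-9):
            raise GeometryError(
                f"{what}: endpoint ({px:.3f}, {py:.3f}) mm outside slice extent "
                f"({bx:.3f} x {by:.3f}) mm"
            )


def make_central_line(
    crestal_slice: int,
    p_start: tuple[float, float],
    p_end: tuple[float, float],
    sampling_width_px: int = DEFAULT_SAMPLING_WIDTH_PX,
    bounds_mm: tuple[float, float] | None = None,
) -> MeasurementLine:
    """Build the central-crestal line, the only manually defined position.

    The line must cross the ridge perpendicular to it and extend beyond the
    ridge width on both sides so that the outer cortical-rim maxima fall well
    inside the profile.
    """
    line = MeasurementLine(
        slice_index=crestal_slice,
        p_start=(float(p_start[0]), float(p_start[1])),
        p_end=(float(p_end[0]), float(p_end[1])),
        sampling_width_px=int(sampling_width_px),
        label=PositionLabel(0.0, CRESTAL),
    )
    _check_bounds(line, bounds_mm, "central line")
    return line


def expand_horizontal(
    central: MeasurementLine,
    offsets_mm: Sequence[float] = DEFAULT_OFFSETS_MM,
    bounds_mm: tuple[float, float] | None = None,
) -> list[MeasurementLine]:
    """Duplicate the central line at the given perpendicular offsets
    (defaults: 1 mm and 2 mm mesially and distally)."""
    if central.label.offset_mm != 0.0:
        raise ParameterError("expand_horizontal expects the central (offset 0) line")
    lines = []
    for off in offsets_mm:
        shifted = central.shifted(float(off))
        try:
            _check_bounds(shifted, bounds_mm, f"offset {off:+g} mm")
        except GeometryError as exc:
            raise GeometryError(str(exc)) from None
        lines.append(shifted)
    return lines


def select_depth_slices(
    crestal_slice: int,
    slice_thickness_mm: float,
    targets_mm: Sequence[float] = DEFAULT_DEPTH_TARGETS_MM,
    tolerance_mm: float = DEFAULT_DEPTH_TOLERANCE_MM,
    depth: int | None = None,
) -> list[int]:
    """Axial indices of the apical measurement planes.

    For each target depth the nearest integer number of slices ``k`` is used
    (a tie between two equally distant slice counts is broken toward the more
    crestal slice), provided the achieved depth ``k * slice_thickness`` stays
    within ``tolerance_mm`` of the target; otherwise a :class:`ToleranceError`
    names the achievable depths.  ``depth`` (stack depth) bounds the result
    when given.
    """
    if slice_thickness_mm <= 0:
        raise ParameterError(f"slice thickness must be positive, got {slice_thickness_mm}")
    if tolerance_mm < 0:
        raise ParameterError(f"tolerance must be non-negative, got {tolerance_mm}")

    indices = []
    for target in targets_mm:
        x = target / slice_thickness_mm
        k_lo = math.floor(x)
        frac = x - k_lo
        k = k_lo + 1 if frac > 0.5 + 1e-9 else k_lo  # tie (frac == 0.5) -> crestal-ward
        achieved = k * slice_thickness_mm
        if abs(achieved - target) > tolerance_mm + 1e-9:
            lo, hi = k_lo * slice_thickness_mm, (k_lo + 1) * slice_thickness_mm
            raise ToleranceError(
                f"no slice within {tolerance_mm} mm of {target} mm depth at "
                f"{slice_thickness_mm} mm thickness (achievable: {lo:g} or {hi:g} mm)"
            )
        index = crestal_slice + k
        if depth is not None and not (0 <= index < depth):
            raise BoundsError(f"depth plane {target} mm maps to slice {index} beyond depth {depth}")
        indices.append(index)
    return indices


@dataclass(frozen=True)
class MeasurementGrid:
    """The full 15-line measurement grid (5 offsets x 3 depth planes)."""

    lines: tuple[MeasurementLine, ...]
    crestal_slice: int
    depth_slices: tuple[int, ...]
    tolerance_mm: float = DEFAULT_DEPTH_TOLERANCE_MM

    def __post_init__(self) -> None:
        lengths = {round(line.length_mm, 9) for line in self.lines}
        if len(lengths) > 1:
            raise GeometryError(f"grid lines are not all equal length: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.lines)

    def __iter__(self):
        return iter(self.lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "crestal_slice": self.crestal_slice,
            "depth_slices": list(self.depth_slices),
            "tolerance_mm": self.tolerance_mm,
            "lines": [line.to_dict() for line in self.lines],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MeasurementGrid":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).is_file()):
            source = Path(source).read_text()
        data = json.loads(source)
        return cls(
            lines=tuple(MeasurementLine.from_dict(d) for d in data["lines"]),
            crestal_slice=int(data["crestal_slice"]),
            depth_slices=tuple(int(i) for i in data["depth_slices"]),
            tolerance_mm=float(data.get("tolerance_mm", DEFAULT_DEPTH_TOLERANCE_MM)),
        )


def build_grid(
    central: MeasurementLine,
    depth_slices: Sequence[int],
    depth_targets_mm: Sequence[float] = DEFAULT_DEPTH_TARGETS_MM,
    offsets_mm: Sequence[float] = DEFAULT_OFFSETS_MM,
    tolerance_mm: float = DEFAULT_DEPTH_TOLERANCE_MM,
    bounds_mm: tuple[float, float] | None = None,
) -> MeasurementGrid:
    """Expand the central crestal line into the full measurement grid.

    The 5 crestal lines are copied verbatim (identical in-plane endpoints)
    onto every depth slice, giving ``(1 + len(offsets)) * (1 + len(depths))``
    positions — 15 with the defaults.  Lines are ordered by (depth, offset)
    so downstream tables are deterministic.
    """
    if len(depth_slices) != len(depth_targets_mm):
        raise ParameterError("depth_slices and depth_targets_mm must pair up")
    crestal = sorted(
        [central, *expand_horizontal(central, offsets_mm, bounds_mm)],
        key=lambda ln: ln.label.offset_mm,
    )
    lines: list[MeasurementLine] = list(crestal)
    for slice_index, target in zip(depth_slices, depth_targets_mm):
        lines.extend(line.on_slice(int(slice_index), float(target)) for line in crestal)
    return MeasurementGrid(
        lines=tuple(lines),
        crestal_slice=central.slice_index,
        depth_slices=tuple(int(i) for i in depth_slices),
        tolerance_mm=tolerance_mm,
    )
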