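"""Region-of-interest reduction and baseline/follow-up co-registration.

The baseline (post-extraction) scan is cropped and rotated interactively once;
the resulting :class:`RoiSpec` is then re-applied verbatim to the follow-up
scan so both timepoints live in one frame.  Residual misalignment is removed
by an exhaustive integer-voxel translation search maximizing normalized
cross-correlation (NCC) — rotational discrepancies between two scans of the
same rigid jaw region are small, so no rotation refinement is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from skimage.feature import match_template

from .errors import BoundsError, CompatibilityError, ParameterError
from .volume_io import VolumeStack, round_half_up

__all__ = [
    "RoiSpec",
    "AlignmentResult",
    "keep_slices",
    "crop_rotate",
    "align_followup",
]


@dataclass(frozen=True)
class RoiSpec:
    """Crop + in-plane rotation applied identically to both timepoints.

    Attributes
    ----------
    slice_range
        (first, last) inclusive axial indices to keep.
    rect
        (row0, col0, height, width) axial crop rectangle in voxels.
    rotation_deg
        In-plane rotation in (-180, 180], applied after cropping about the
        rectangle centre; positive angles rotate image content
        counter-clockwise (rows displayed top-down).
    """

    slice_range: tuple[int, int]
    rect: tuple[int, int, int, int]
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (-180.0 < self.rotation_deg <= 180.0):
            raise ParameterError(f"rotation_deg must be in (-180, 180], got {self.rotation_deg}")
        if self.rect[2] <= 0 or self.rect[3] <= 0:
            raise BoundsError(f"empty crop rectangle {self.rect}")

    def validate_for(self, stack: VolumeStack) -> None:
        first, last = self.slice_range
        if not (0 <= first <= last < stack.depth):
            raise BoundsError(f"slice range {self.slice_range} outside depth {stack.depth}")
        r0, c0, h, w = self.rect
        _, rows, cols = stack.shape
        if r0 < 0 or c0 < 0 or r0 + h > rows or c0 + w > cols:
            raise BoundsError(f"rect {self.rect} outside slice {rows}x{cols}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RoiSpec":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            slice_range=tuple(data["slice_range"]),
            rect=tuple(data["rect"]),
            rotation_deg=float(data.get("rotation_deg", 0.0)),
        )


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of the translation refinement.

    ``translation_voxels`` is the (dz, dy, dx) shift applied to the follow-up;
    ``score`` is the NCC at the optimum; ``low_score`` flags a score under the
    configured floor so users can review the registration.
    """

    translation_voxels: tuple[int, int, int]
    score: float
    low_score: bool = False


def keep_slices(stack: VolumeStack, first: int, last: int) -> VolumeStack:
    """Retain axial slices ``first..last`` (inclusive); the Slice-Keeper step
    that removes irrelevant apical/coronal anatomy."""
    if not (0 <= first <= last < stack.depth):
        raise BoundsError(
            f"keep_slices range ({first}, {last}) invalid for depth {stack.depth}"
        )
    return stack.evolve(stack.voxels[first : last + 1].copy(), f"keep_slices[{first}:{last}]")


def _rotate_volume(voxels: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate every axial slice by ``angle_deg`` CCW about the slice centre,
    bilinear interpolation, zero fill; integer grey values are re-rounded
    half-up so repeated runs are bit-identical."""
    rotated = ndimage.rotate(
        voxels.astype(np.float64),
        angle_deg,
        axes=(2, 1),  # rotate within the (row, col) plane, CCW for angle > 0
        reshape=False,
        order=1,
        mode="constant",
        cval=0.0,
    )
    if np.issubdtype(voxels.dtype, np.integer):
        info = np.iinfo(voxels.dtype)
        return np.clip(round_half_up(rotated), info.min, info.max).astype(voxels.dtype)
    return rotated.astype(voxels.dtype)


def crop_rotate(stack: VolumeStack, roi: RoiSpec) -> VolumeStack:
    """Apply the ROI: keep slices, crop the axial rectangle, then rotate
    in-plane about the rectangle centre.  Voxel size is unchanged (rigid
    in-plane transform)."""
    roi.validate_for(stack)
    z0, z1 = roi.slice_range
    r0, c0, h, w = roi.rect
    sub = stack.voxels[z0 : z1 + 1, r0 : r0 + h, c0 : c0 + w].copy()
    if roi.rotation_deg != 0.0:
        sub = _rotate_volume(sub, roi.rotation_deg)
    return stack.evolve(
        sub,
        f"crop_rotate[slices={roi.slice_range}, rect={roi.rect}, rot={roi.rotation_deg:g}]",
    )


def _integer_shift(voxels: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    """Shift with zero fill (no wrap-around)."""
    out = np.zeros_like(voxels)
    src = []
    dst = []
    for axis, s in enumerate(shift):
        n = voxels.shape[axis]
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = voxels[tuple(src)]
    return out


def align_followup(
    reference: VolumeStack,
    followup_raw: VolumeStack,
    roi: RoiSpec,
    search_radius_voxels: tuple[int, int, int] = (3, 10, 10),
    score_floor: float = 0.5,
) -> tuple[VolumeStack, AlignmentResult]:
    """Bring the follow-up scan into the baseline frame.

    The baseline ROI is re-applied to the follow-up, which is then refined by
    the integer translation (within ``search_radius_voxels`` per axis, (z, y,
    x)) that maximizes NCC against the reference.  The search is exhaustive —
    the cropped sockets are small, so brute force is cheap and exactly
    reproducible.  NCC is computed for every candidate placement at once via
    :func:`skimage.feature.match_template` on the zero-padded moving volume,
    which is algebraically identical to scoring each zero-filled shift.

    Ties in the score are broken toward the smallest shift (L1 norm, then
    lexicographic), so self-alignment returns (0, 0, 0).
    """
    if not np.allclose(reference.voxel_size, followup_raw.voxel_size, atol=1e-9):
        raise CompatibilityError(
            f"voxel sizes differ: {reference.voxel_size} vs {followup_raw.voxel_size}"
        )
    moving = crop_rotate(followup_raw, roi)
    if moving.shape != reference.shape:
        raise CompatibilityError(f"ROI produced shapes {moving.shape} vs {reference.shape}")

    radius = tuple(int(r) for r in search_radius_voxels)
    if any(r < 0 for r in radius):
        raise ParameterError(f"negative search radius {radius}")

    ref = reference.voxels.astype(np.float64)
    if float(ref.std()) == 0.0:
        result = AlignmentResult((0, 0, 0), 0.0, low_score=True)
        return moving.evolve(moving.voxels.copy(), "align_followup[degenerate reference]"), result

    padded = np.pad(moving.voxels.astype(np.float64), [(r, r) for r in radius])
    ncc = match_template(padded, ref)  # shape (2r+1,) per axis

    best = float(np.nanmax(ncc))
    candidates = np.argwhere(ncc >= best - 1e-12)
    shifts = [tuple(int(r - o) for r, o in zip(radius, off)) for off in candidates]
    translation = min(shifts, key=lambda t: (sum(abs(s) for s in t), t))

    aligned_voxels = _integer_shift(moving.voxels, translation)
    aligned = moving.evolve(
        aligned_voxels,
        f"align_followup[shift={translation}, ncc={best:.4f}]",
    )
    return aligned, AlignmentResult(translation, best, low_score=best < score_floor)
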