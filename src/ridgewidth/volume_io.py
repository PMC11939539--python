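"""CBCT volume I/O: DICOM series in, 8-bit TIFF stacks for interchange.

The central container is :class:`VolumeStack`: a 3-D grey-value array in
(axial slice, row, column) order together with the physical voxel size in mm
and a provenance trail of the transforms applied to it.

Coordinate conventions
----------------------
Voxel indices are 0-based.  Slice index 0 is the most coronal/crestal slice
retained and the index increases apically.  Millimetre coordinates are
measured from the centre of voxel (0, 0, 0); in-plane points are (x, y) =
(column_mm, row_mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
import tifffile
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import InputError, MetadataError, SeriesError

__all__ = [
    "VolumeStack",
    "load_dicom_series",
    "normalize_to_8bit",
    "write_tiff_stack",
    "read_tiff_stack",
    "write_dicom_series",
]

_CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"


def round_half_up(values: np.ndarray) -> np.ndarray:
    """Round to the nearest integer, halves away from zero-wards up.

    ``numpy.round`` rounds halves to even; peak heights must be bit-exact
    across platforms, so the rounding rule is pinned here once.
    """
    return np.floor(np.asarray(values, dtype=np.float64) + 0.5)


@dataclass
class VolumeStack:
    """A 3-D grey-value volume with voxel-size metadata and provenance.

    Parameters
    ----------
    voxels
        Array of shape (slices, rows, cols).
    voxel_size
        (slice_thickness_mm, row_spacing_mm, col_spacing_mm); all > 0.
    bit_depth
        Bit depth of the source data (grey values after 8-bit
        normalization lie in [0, 255]).
    axial_increases_apically
        True when slice index 0 is the most crestal slice retained.
    provenance
        Ordered list of transform descriptions; never shrinks.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    bit_depth: int = 8
    axial_increases_apically: bool = True
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise InputError(f"expected 3-D voxel array, got {self.voxels.ndim}-D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise MetadataError(f"voxel size must be three positive values, got {self.voxel_size}")

    # -- convenience -------------------------------------------------------
    @property
    def depth(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    @property
    def in_plane_pitch(self) -> float:
        """Isotropic in-plane sample pitch (mm); row and column spacing
        must agree to 1e-6 mm (true for CBCT reconstructions)."""
        _, dy, dx = self.voxel_size
        if abs(dy - dx) > 1e-6:
            raise MetadataError(f"anisotropic in-plane spacing {dy} x {dx} mm")
        return dx

    @property
    def plane_extent_mm(self) -> tuple[float, float]:
        """(x_max, y_max): the in-plane coordinate of the last voxel centre."""
        _, rows, cols = self.shape
        return ((cols - 1) * self.voxel_size[2], (rows - 1) * self.voxel_size[1])

    def evolve(self, voxels: np.ndarray, step: str, **changes) -> "VolumeStack":
        """Copy with new voxels and one appended provenance entry."""
        return replace(
            self,
            voxels=voxels,
            provenance=[*self.provenance, step],
            **changes,
        )


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def _slice_position(ds: Dataset) -> float:
    """Scan-axis position of one slice, from ImagePositionPatient projected
    onto the slice normal, with InstanceNumber as a last resort."""
    ipp = getattr(ds, "ImagePositionPatient", None)
    iop = getattr(ds, "ImageOrientationPatient", None)
    if ipp is not None and iop is not None:
        row = np.asarray(iop[:3], dtype=float)
        col = np.asarray(iop[3:], dtype=float)
        normal = np.cross(row, col)
        return float(np.dot(normal, np.asarray(ipp, dtype=float)))
    if ipp is not None:
        return float(ipp[2])
    number = getattr(ds, "InstanceNumber", None)
    if number is None:
        raise MetadataError("slice has neither ImagePositionPatient nor InstanceNumber")
    return float(number)


def load_dicom_series(directory: str | Path) -> VolumeStack:
    """Read a single-frame DICOM series into a :class:`VolumeStack`.

    Slices are sorted by spatial position along the scan axis, so the result
    is independent of on-disk file names.  Grey values are preserved at the
    source bit depth.

    Raises
    ------
    InputError
        Empty directory / no readable DICOM files.
    SeriesError
        Files from more than one SeriesInstanceUID.
    MetadataError
        Missing or contradictory spacing attributes.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    datasets = []
    for f in sorted(directory.iterdir()):
        if not f.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:  # not a DICOM file
            continue
    if not datasets:
        raise InputError(f"no DICOM slices found in {directory}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise SeriesError(f"mixed series identifiers in {directory}: {sorted(map(str, uids))}")

    datasets.sort(key=_slice_position)

    first = datasets[0]
    spacing = getattr(first, "PixelSpacing", None)
    if spacing is None:
        raise MetadataError("PixelSpacing attribute missing")
    row_mm, col_mm = float(spacing[0]), float(spacing[1])

    thickness = getattr(first, "SliceThickness", None)
    if len(datasets) >= 2:
        positions = np.array([_slice_position(ds) for ds in datasets])
        steps = np.diff(positions)
        if np.any(steps <= 0):
            raise MetadataError("duplicate or non-monotone slice positions")
        dz = float(np.median(steps))
        if thickness is not None and abs(dz - float(thickness)) > 0.05 * max(dz, float(thickness)):
            raise MetadataError(
                f"slice spacing {dz:.4f} mm contradicts SliceThickness {float(thickness):.4f} mm"
            )
    elif thickness is not None:
        dz = float(thickness)
    else:
        raise MetadataError("single slice without SliceThickness")

    voxels = np.stack([ds.pixel_array for ds in datasets])
    bit_depth = int(getattr(first, "BitsStored", voxels.dtype.itemsize * 8))
    return VolumeStack(
        voxels=voxels,
        voxel_size=(dz, row_mm, col_mm),
        bit_depth=bit_depth,
        provenance=[f"load_dicom_series[{directory.name}, {len(datasets)} slices]"],
    )


def write_dicom_series(
    stack: VolumeStack,
    directory: str | Path,
    *,
    series_description: str = "ridgewidth volume",
    uid_entropy: str | None = None,
) -> list[Path]:
    """Write the stack as an uncompressed single-frame DICOM series.

    ``uid_entropy`` makes all generated UIDs deterministic, so fixtures are
    reproducible byte-for-byte in their pixel data and identifiers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dz, dy, dx = stack.voxel_size

    voxels = np.ascontiguousarray(stack.voxels)
    if voxels.dtype == np.uint8:
        bits = 8
    elif voxels.dtype == np.uint16:
        bits = 16
    else:
        raise MetadataError(f"unsupported dtype for DICOM export: {voxels.dtype}")

    def _uid(tag: str) -> str:
        srcs = None if uid_entropy is None else [f"{uid_entropy}/{tag}"]
        return generate_uid(entropy_srcs=srcs)

    study_uid = _uid("study")
    series_uid = _uid("series")
    paths: list[Path] = []
    for i in range(stack.depth):
        ds = Dataset()
        ds.SOPClassUID = _CT_STORAGE
        ds.SOPInstanceUID = _uid(f"slice{i}")
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = series_description
        ds.Modality = "CT"
        ds.PatientName = "synthetic^phantom"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, round(i * dz, 6)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [round(dy, 6), round(dx, 6)]
        ds.SliceThickness = round(dz, 6)
        ds.Rows, ds.Columns = voxels.shape[1], voxels.shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = bits
        ds.BitsStored = bits
        ds.HighBit = bits - 1
        ds.PixelRepresentation = 0
        ds.PixelData = voxels[i].tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta

        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# 8-bit normalization
# ---------------------------------------------------------------------------

def normalize_to_8bit(stack: VolumeStack) -> VolumeStack:
    """Linear whole-stack min-max rescale onto [0, 255].

    The window is global (not per slice): the ridge width depends only on
    *where* the grey-value maxima sit, and a single monotone map preserves
    every peak location while keeping slices mutually comparable.  Values are
    rounded half-up; a constant-valued stack maps to all zeros.
    """
    v = stack.voxels.astype(np.float64)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        out = np.zeros_like(v, dtype=np.uint8)
    else:
        out = round_half_up((v - lo) * (255.0 / (hi - lo))).astype(np.uint8)
    return stack.evolve(
        out,
        f"normalize_to_8bit[window=({lo:g},{hi:g})]",
        bit_depth=8,
    )


# ---------------------------------------------------------------------------
# TIFF interchange
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_tiff_stack(stack: VolumeStack, path: str | Path) -> Path:
    """Write a normalized stack as a multi-page 8-bit grayscale TIFF.

    Voxel size and provenance go to a JSON sidecar next to the TIFF (TIFF
    resolution tags cannot carry the axial spacing losslessly).
    """
    path = Path(path)
    voxels = stack.voxels
    if voxels.dtype != np.uint8:
        raise MetadataError("write_tiff_stack expects an 8-bit (normalized) stack")
    tifffile.imwrite(path, voxels, photometric="minisblack")
    sidecar = {
        "voxel_size_mm": list(stack.voxel_size),
        "bit_depth": stack.bit_depth,
        "axial_increases_apically": stack.axial_increases_apically,
        "provenance": list(stack.provenance),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_tiff_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
) -> VolumeStack:
    """Read a multi-page TIFF stack back into a :class:`VolumeStack`.

    A caller-supplied ``voxel_size`` is authoritative and always wins over
    whatever the file (sidecar) claims — the "verify and readjust" step for
    stacks whose metadata was mangled on export.  Without a caller value the
    sidecar is used; if neither exists the voxel size is unknown and a
    :class:`MetadataError` is raised.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such file: {path}")
    voxels = tifffile.imread(path)
    if voxels.ndim == 2:
        voxels = voxels[None]

    sidecar_file = _sidecar_path(path)
    sidecar = json.loads(sidecar_file.read_text()) if sidecar_file.is_file() else {}
    file_size = sidecar.get("voxel_size_mm")

    if voxel_size is not None:
        size = tuple(float(v) for v in voxel_size)
        note = "caller" if file_size is None or tuple(file_size) == size else "caller-override"
    elif file_size is not None:
        size = tuple(float(v) for v in file_size)
        note = "sidecar"
    else:
        raise MetadataError(f"voxel size unknown for {path}; pass voxel_size explicitly")

    provenance = list(sidecar.get("provenance", []))
    provenance.append(f"read_tiff_stack[{path.name}, voxel_size={note}]")
    return VolumeStack(
        voxels=voxels,
        voxel_size=size,  # type: ignore[arg-type]
        bit_depth=int(sidecar.get("bit_depth", 8)),
        axial_increases_apically=bool(sidecar.get("axial_increases_apically", True)),
        provenance=provenance,
    )
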