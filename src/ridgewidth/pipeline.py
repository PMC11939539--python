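"""End-to-end orchestration: preprocess -> grid -> measure x2 -> compare.

The semi-automation boundary mirrors the workflow this package implements:
the only manual inputs are the ROI (crop/rotation) and the central crestal
line; everything downstream — grid expansion, depth-plane selection, profile
measurement, change tables — is automatic and deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import grid as grid_mod
from . import preprocess, stats, volume_io, width
from .errors import InputError

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("ridgewidth")


@dataclass
class RunConfig:
    """Validated configuration for one scan-pair run."""

    t0_dir: Path
    t1_dir: Path
    out_dir: Path
    central_line: grid_mod.MeasurementLine
    roi: preprocess.RoiSpec | None = None  # None -> whole volume, no rotation
    offsets_mm: tuple[float, ...] = grid_mod.DEFAULT_OFFSETS_MM
    depth_targets_mm: tuple[float, ...] = grid_mod.DEFAULT_DEPTH_TARGETS_MM
    depth_tolerance_mm: float = grid_mod.DEFAULT_DEPTH_TOLERANCE_MM
    prominence_fraction: float = width.DEFAULT_PROMINENCE_FRACTION
    search_radius_voxels: tuple[int, int, int] = (3, 10, 10)
    scan_pair_id: str = "pair"

    def validate(self) -> None:
        for name, p in (("t0", self.t0_dir), ("t1", self.t1_dir)):
            if not Path(p).is_dir():
                raise InputError(f"{name} directory does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        resolve = lambda p: (base / p) if not Path(p).is_absolute() else Path(p)
        central = grid_mod.MeasurementLine.from_dict(
            json.loads(resolve(data["central_line"]).read_text())
            if isinstance(data["central_line"], str)
            else data["central_line"]
        )
        roi = None
        if data.get("roi"):
            roi = preprocess.RoiSpec.from_yaml(resolve(data["roi"]))
        return cls(
            t0_dir=resolve(data["t0"]),
            t1_dir=resolve(data["t1"]),
            out_dir=resolve(data.get("out", "ridgewidth_out")),
            central_line=central,
            roi=roi,
            offsets_mm=tuple(data.get("offsets_mm", grid_mod.DEFAULT_OFFSETS_MM)),
            depth_targets_mm=tuple(data.get("depth_targets_mm", grid_mod.DEFAULT_DEPTH_TARGETS_MM)),
            depth_tolerance_mm=float(data.get("depth_tolerance_mm", grid_mod.DEFAULT_DEPTH_TOLERANCE_MM)),
            prominence_fraction=float(data.get("prominence_fraction", width.DEFAULT_PROMINENCE_FRACTION)),
            scan_pair_id=str(data.get("scan_pair_id", "pair")),
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order, writing per-stage intermediates.

    Outputs under ``config.out_dir``: normalized/aligned TIFF stacks,
    ``grid.json``, per-timepoint measurement CSVs, ``change.csv``,
    ``summary.csv`` and a JSON run report.  Returns the report dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("loading DICOM series")
    raw0 = volume_io.load_dicom_series(config.t0_dir)
    raw1 = volume_io.load_dicom_series(config.t1_dir)
    stack0 = volume_io.normalize_to_8bit(raw0)
    stack1 = volume_io.normalize_to_8bit(raw1)

    roi = config.roi or preprocess.RoiSpec(
        slice_range=(0, stack0.depth - 1),
        rect=(0, 0, stack0.shape[1], stack0.shape[2]),
        rotation_deg=0.0,
    )
    reference = preprocess.crop_rotate(stack0, roi)
    aligned, alignment = preprocess.align_followup(
        reference, stack1, roi, config.search_radius_voxels
    )
    log.info("alignment: shift=%s ncc=%.4f", alignment.translation_voxels, alignment.score)
    volume_io.write_tiff_stack(reference, out / "t0_reference.tif")
    volume_io.write_tiff_stack(aligned, out / "t1_aligned.tif")

    depth_slices = grid_mod.select_depth_slices(
        config.central_line.slice_index,
        reference.voxel_size[0],
        config.depth_targets_mm,
        config.depth_tolerance_mm,
        depth=reference.depth,
    )
    achieved = [
        (s - config.central_line.slice_index) * reference.voxel_size[0] for s in depth_slices
    ]
    log.info("depth planes: slices %s, achieved depths %s mm", depth_slices, achieved)
    measurement_grid = grid_mod.build_grid(
        config.central_line,
        depth_slices,
        config.depth_targets_mm,
        config.offsets_mm,
        config.depth_tolerance_mm,
        bounds_mm=reference.plane_extent_mm,
    )
    measurement_grid.to_json(out / "grid.json")

    m0 = width.measure_grid(reference, measurement_grid, config.prominence_fraction)
    m1 = width.measure_grid(aligned, measurement_grid, config.prominence_fraction)
    f0 = width.measurements_to_frame(m0, config.scan_pair_id, "t0")
    f1 = width.measurements_to_frame(m1, config.scan_pair_id, "t1")
    f0.to_csv(out / "measurements_t0.csv", index=False)
    f1.to_csv(out / "measurements_t1.csv", index=False)
    for frame, tp in ((f0, "t0"), (f1, "t1")):
        flagged = frame[frame["flags"] != ""]
        for _, row in flagged.iterrows():
            log.warning("%s (%+g mm, %s): flags %s", tp, row.offset_mm, row.depth_level, row.flags)

    records = stats.width_change(m0, m1, config.scan_pair_id)
    change = stats.records_to_frame(records)
    change.to_csv(out / "change.csv", index=False)
    summary = stats.summarize_positions(records)
    summary.to_csv(out / "summary.csv", index=False)

    report = {
        "scan_pair_id": config.scan_pair_id,
        "alignment": {
            "translation_voxels": list(alignment.translation_voxels),
            "ncc_score": alignment.score,
            "low_score": alignment.low_score,
        },
        "depth_slices": list(map(int, depth_slices)),
        "achieved_depths_mm": achieved,
        "n_positions": len(measurement_grid),
        "n_unmeasurable": int(change["loss_mm"].isna().sum()),
        "prominence_fraction": config.prominence_fraction,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
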