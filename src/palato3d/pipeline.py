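"""End-to-end orchestration: segment -> register -> partition -> deviate -> report.

A :class:`PipelineConfig` (JSON/TOML file or constructed in code) is the
single source of truth for one run; the effective config, package versions,
seed, per-stage timings and counts are echoed into the output directory, and
re-running an identical config reproduces the report CSV byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import LandmarkSet, TriangleMesh, VoxelGrid, read_mesh, write_mesh
from .deviation import (
    REPORT_COLUMNS,
    RoiReport,
    compute_distance_field,
    export_distance_map,
    roi_report,
)
from .errors import ValidationError
from .registration import register
from .roi import ROI_NAMES, RoiParams, build_roi_labels
from .segmentation import SegmentationParams, segment_volume
from .stats import StatsTable, pairwise_roi_tests

log = logging.getLogger("palato3d")

_METRIC_FIELDS = {"MeanDist": "mean_mm", "Vol": "vol_mm3"}


@dataclass
class PipelineConfig:
    """Inputs and stage parameters for one patient run.

    Exactly one of ``volume`` (HU grid, segmented in-run) or ``bone_mesh``
    must be provided. ``landmarks`` travel with the gingiva (source) frame;
    ``landmarks_bone`` defaults to the same file when the frames coincide.
    """

    gingiva_mesh: str = ""
    bone_mesh: str | None = None
    volume: str | None = None
    volume_meta: str | None = None
    landmarks: str = ""
    landmarks_bone: str | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tooth_radius: float = 5.0
    icp_tol: float = 1e-4
    icp_max_iter: int = 100
    roi: RoiParams = field(default_factory=RoiParams)
    max_distance: float = 15.0
    max_angle: float = 60.0
    scale_max: float = 5.0
    out_dir: str = "palato3d_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.bone_mesh is None) == (self.volume is None):
            raise ValidationError("provide exactly one of bone_mesh or volume")
        for path in (self.gingiva_mesh, self.landmarks, self.bone_mesh, self.volume,
                     self.landmarks_bone, self.volume_meta):
            if path and not Path(path).exists():
                raise ValidationError(f"input file not found: {path}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            payload = tomllib.loads(path.read_text())
        else:
            payload = json.loads(path.read_text())
        seg = SegmentationParams(**payload.pop("segmentation", {}))
        roi = RoiParams(**payload.pop("roi", {}))
        return cls(segmentation=seg, roi=roi, **payload)

    def echo(self) -> dict:
        d = asdict(self)
        d["roi"]["boundary_names"] = list(d["roi"]["boundary_names"])
        return d


def _load_bone(config: PipelineConfig) -> TriangleMesh:
    if config.bone_mesh:
        return read_mesh(config.bone_mesh)
    if str(config.volume).endswith((".nii", ".nii.gz")):
        grid = VoxelGrid.from_nifti(config.volume)
    else:
        if not config.volume_meta:
            raise ValidationError("raw .npy volume needs volume_meta JSON (spacing/origin)")
        grid = VoxelGrid.from_npy(config.volume, config.volume_meta)
    return segment_volume(grid, config.segmentation)


def run_pipeline(config: PipelineConfig, objects: dict | None = None):
    """Run all stages; write artifacts to ``config.out_dir``; return (report, artifacts).

    ``objects`` may inject in-memory inputs (keys ``gingiva``, ``bone``,
    ``landmarks``, ``landmarks_bone``) for library use; file paths are used
    otherwise. Any stage error propagates tagged with the stage name.
    """
    objects = objects or {}
    if not objects:
        config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {
        "package": "palato3d",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config": config.echo(),
        "stages": {},
    }
    artifacts: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                run_log["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 4)
                }
                if exc is not None:
                    run_log["stages"][name]["error"] = repr(exc)
                    run_log["incomplete"] = True
                    (out / "run.json").write_text(json.dumps(run_log, indent=2))
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Timer()

    with stage("inputs"):
        gingiva = objects.get("gingiva") or read_mesh(config.gingiva_mesh)
        bone = objects.get("bone") or _load_bone(config)
        lms = objects.get("landmarks") or LandmarkSet.from_json(config.landmarks)
        lms_bone = objects.get("landmarks_bone") or (
            LandmarkSet.from_json(config.landmarks_bone) if config.landmarks_bone else lms
        )
        run_log["stages"]["inputs"] = {
            "gingiva_faces": len(gingiva.faces),
            "bone_faces": len(bone.faces),
        }

    with stage("register"):
        reg = register(
            gingiva, bone, lms, lms_bone,
            tooth_radius=config.tooth_radius, tol=config.icp_tol,
            max_iter=config.icp_max_iter, seed=config.seed,
        )
        gingiva_reg = TriangleMesh(
            vertices=reg.transform.apply(gingiva.vertices), faces=gingiva.faces.copy(),
            process=False,
        )
        lms_reg = lms.transform(reg.transform)
        reg.transform.to_json(out / "transform.json")
        run_log["stages"]["register"] = {
            "rms_mm": reg.rms, "iterations": reg.iterations, "converged": reg.converged,
        }
        artifacts["transform"] = reg

    with stage("partition"):
        labels = build_roi_labels(gingiva_reg, lms_reg, config.roi)
        labels.to_csv(out / "roi_labels.csv")
        run_log["stages"]["partition"] = {
            "included_faces": int(labels.included.sum()),
            "per_roi_faces": {n: int(len(labels.faces_of(i + 1))) for i, n in enumerate(ROI_NAMES)},
        }
        artifacts["labels"] = labels

    with stage("deviate"):
        fld = compute_distance_field(
            gingiva_reg, bone, max_distance=config.max_distance, max_angle=config.max_angle
        )
        report = roi_report(fld, labels, gingiva_reg)
        export_distance_map(fld, gingiva_reg, config.scale_max, out / "distance_map.ply")
        report.to_csv(out / "report.csv")
        report.to_json(out / "report.json")
        run_log["stages"]["deviate"] = {
            "valid_vertices": int(fld.valid.sum()),
            "invalid_vertices": int((~fld.valid).sum()),
        }
        artifacts["field"] = fld
        artifacts["report"] = report

    (out / "run.json").write_text(json.dumps(run_log, indent=2))
    artifacts["run_log"] = run_log
    return report, artifacts


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Across-patient mean and sd of every report field, per ROI and total."""

    mean: pd.DataFrame
    sd: pd.DataFrame | None
    n_patients: int

    def to_csv(self, path) -> None:
        frame = self.mean.copy()
        frame.insert(1, "stat", "mean")
        if self.sd is not None:
            sd = self.sd.copy()
            sd.insert(1, "stat", "sd")
            frame = pd.concat([frame, sd], ignore_index=True)
        frame.to_csv(path, index=False, float_format="%.9g")


def aggregate_cohort(reports: list) -> tuple:
    """Cohort descriptive statistics + pairwise ROI tests (MeanDist and Vol).

    Pairwise Wilcoxon tests run only with >= 6 patients (below that the
    two-sided exact p cannot fall under 0.05). Raises on inconsistent ROI
    sets; sd is reported only for n >= 2.
    """
    if not reports:
        raise ValidationError("empty cohort")
    frames = [r.to_frame() for r in reports]
    ref_rois = list(frames[0]["roi"])
    bad = [i for i, f in enumerate(frames) if list(f["roi"]) != ref_rois]
    if bad:
        raise ValidationError(f"inconsistent ROI sets for patients {bad}")
    stack = pd.concat(frames, keys=range(len(frames)), names=["patient"]).reset_index(0)
    grouped = stack.groupby("roi", sort=False)
    mean = grouped.mean(numeric_only=True).reset_index()
    mean = mean.reindex(columns=REPORT_COLUMNS)
    n = len(reports)
    sd = None
    if n >= 2:
        sd = grouped.std(ddof=1, numeric_only=True).reset_index()
        sd = sd.reindex(columns=REPORT_COLUMNS)
    summary = CohortSummary(mean, sd, n)

    tests: dict[str, StatsTable] = {}
    if n >= 6:
        for metric, col in _METRIC_FIELDS.items():
            values = {}
            ok = True
            for roi in ROI_NAMES:
                v = stack.loc[stack["roi"] == roi, col].to_numpy()
                if np.isnan(v).any():
                    ok = False
                v = np.nan_to_num(v)
                values[roi] = v
            if ok:
                tests[metric] = pairwise_roi_tests(values)
    return summary, tests
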