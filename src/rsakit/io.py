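"""File formats: marker tables, cage models, detections, results, manifests.

All tabular interchange is plain CSV with millimetre coordinates and a
period decimal separator; cage models and study manifests are JSON;
scenarios and threshold overrides are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationCage, ImageDetections
from .geometry import MarkerObservation, RigidBodyObservation
from .migration import Examination, MigrationResult
from .quality import QCThresholds

__all__ = [
    "read_cage_json", "write_cage_json",
    "read_detections_csv", "write_detections_csv",
    "read_marker_table", "write_marker_table",
    "examinations_from_tables", "write_results_csv", "read_results_csv",
    "read_thresholds_yaml", "read_scenario_yaml",
    "write_manifest_json", "read_manifest_json",
]

RESULT_COLUMNS = [
    "patient_id", "baseline_exam_id", "followup_exam_id", "body_id",
    "days_since_surgery",
    "tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg",
    "tt_mm", "tr_deg", "mtpm_mm", "mtpm_point",
    "me_ref_mm", "me_mov_mm", "cn_ref", "cn_mov",
    "n_markers_ref", "n_markers_mov",
    "marker_method", "side", "side_convention", "warnings",
]


def read_cage_json(path: str | Path) -> CalibrationCage:
    data = json.loads(Path(path).read_text())
    return CalibrationCage(
        cage_type=data["cage_type"],
        fiducials={m["id"]: np.array([m["x"], m["y"], m["z"]]) for m in data["fiducials"]},
        controls={m["id"]: np.array([m["x"], m["y"], m["z"]]) for m in data["controls"]},
        beam_angle_deg=data.get("beam_angle_deg"),
    )


def write_cage_json(cage: CalibrationCage, path: str | Path) -> None:
    data = {
        "cage_type": cage.cage_type,
        "beam_angle_deg": cage.beam_angle_deg,
        "fiducials": [
            {"id": k, "x": float(v[0]), "y": float(v[1]), "z": float(v[2])}
            for k, v in sorted(cage.fiducials.items())
        ],
        "controls": [
            {"id": k, "x": float(v[0]), "y": float(v[1]), "z": float(v[2])}
            for k, v in sorted(cage.controls.items())
        ],
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def read_detections_csv(path: str | Path) -> dict[str, ImageDetections]:
    """Read per-image detections: columns image_id, marker_id, u_mm, v_mm."""
    df = pd.read_csv(path, dtype={"image_id": str, "marker_id": str})
    out: dict[str, ImageDetections] = {}
    for image_id, sub in df.groupby("image_id", sort=True):
        points = {
            row.marker_id: np.array([row.u_mm, row.v_mm])
            for row in sub.itertuples()
        }
        dpi = float(sub["dpi"].iloc[0]) if "dpi" in sub.columns else 150.0
        depth = int(sub["bit_depth"].iloc[0]) if "bit_depth" in sub.columns else 8
        out[str(image_id)] = ImageDetections(str(image_id), points, dpi=dpi, bit_depth=depth)
    return out


def write_detections_csv(detections: Iterable[ImageDetections], path: str | Path) -> None:
    rows = []
    for det in detections:
        for mid in sorted(det.points):
            uv = det.points[mid]
            rows.append({
                "image_id": det.image_id, "marker_id": mid,
                "u_mm": float(uv[0]), "v_mm": float(uv[1]),
                "dpi": det.dpi, "bit_depth": det.bit_depth,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_marker_table(exams: Iterable[Examination], path: str | Path) -> None:
    """Write examinations as the standard marker-coordinate table."""
    rows = []
    for exam in exams:
        for body_id in sorted(exam.bodies):
            body = exam.bodies[body_id]
            for m in body.markers:
                rows.append({
                    "exam_id": exam.exam_id, "body_id": body_id,
                    "marker_id": m.marker_id, "role": m.role,
                    "x_mm": m.position[0], "y_mm": m.position[1], "z_mm": m.position[2],
                    "frame": body.frame,
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_marker_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"exam_id": str, "body_id": str, "marker_id": str})
    required = {"exam_id", "body_id", "marker_id", "x_mm", "y_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    return df


def examinations_from_tables(
    marker_table: pd.DataFrame,
    exam_meta: Mapping[str, Mapping] | None = None,
) -> list[Examination]:
    """Build :class:`Examination` objects from a marker table.

    ``exam_meta`` maps exam_id to metadata (patient_id, side,
    days_since_surgery, kind, modality); absent entries fall back to
    neutral defaults so that a bare coordinate table remains usable.
    """
    exam_meta = exam_meta or {}
    exams: list[Examination] = []
    for exam_id, sub in marker_table.groupby("exam_id", sort=True):
        bodies: dict[str, RigidBodyObservation] = {}
        for body_id, bsub in sub.groupby("body_id", sort=True):
            markers = [
                MarkerObservation(
                    row.marker_id,
                    np.array([row.x_mm, row.y_mm, row.z_mm]),
                    role=getattr(row, "role", "bone") if "role" in bsub.columns else "bone",
                )
                for row in bsub.itertuples()
            ]
            frame = str(bsub["frame"].iloc[0]) if "frame" in bsub.columns else "RSA_GLOBAL"
            bodies[str(body_id)] = RigidBodyObservation(str(body_id), markers, frame=frame)
        meta = dict(exam_meta.get(str(exam_id), {}))
        exams.append(Examination(
            exam_id=str(exam_id),
            patient_id=str(meta.get("patient_id", exam_id)),
            side=meta.get("side", "right"),
            days_since_surgery=int(meta.get("days_since_surgery", 0)),
            bodies=bodies,
            modality=meta.get("modality", "RSA"),
            kind=meta.get("kind", "followup"),
            metadata=meta,
        ))
    return exams


def write_results_csv(results: Iterable[MigrationResult], path: str | Path) -> None:
    """One row per (patient, timepoint, body), full precision."""
    rows = []
    for r in results:
        rows.append({
            "patient_id": r.patient_id,
            "baseline_exam_id": r.baseline_exam_id,
            "followup_exam_id": r.followup_exam_id,
            "body_id": r.body_id,
            "days_since_surgery": r.days_since_surgery,
            "tx_mm": r.tx, "ty_mm": r.ty, "tz_mm": r.tz,
            "rx_deg": r.rx, "ry_deg": r.ry, "rz_deg": r.rz,
            "tt_mm": r.tt, "tr_deg": r.tr, "mtpm_mm": r.mtpm,
            "mtpm_point": r.mtpm_point,
            "me_ref_mm": r.quality_reference.me, "me_mov_mm": r.quality_migrating.me,
            "cn_ref": r.quality_reference.cn, "cn_mov": r.quality_migrating.cn,
            "n_markers_ref": r.quality_reference.n_markers,
            "n_markers_mov": r.quality_migrating.n_markers,
            "marker_method": r.marker_method,
            "side": r.side,
            "side_convention": r.side_convention,
            "warnings": "; ".join(r.warnings),
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    # metadata header documenting the axis conventions
    with open(path, "w") as fh:
        fh.write("# axes: X medial, Y superior, Z anterior (right-side convention); "
                 "rotations right-handed, body-fixed XYZ, degrees\n")
        df.to_csv(fh, index=False)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_thresholds_yaml(path: str | Path) -> QCThresholds:
    """Load threshold overrides; unspecified fields keep guideline defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(QCThresholds.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown threshold fields: {sorted(unknown)}")
    return QCThresholds(**data)


def read_scenario_yaml(path: str | Path):
    """Load a study scenario for :func:`rsakit.phantom.gen_study`."""
    from .phantom import StudyGroup, StudyScenario

    data = yaml.safe_load(Path(path).read_text())
    groups = [StudyGroup(**g) for g in data.pop("groups")]
    if "timepoints_days" in data:
        data["timepoints_days"] = tuple(data["timepoints_days"])
    if "baseline_day_range" in data:
        data["baseline_day_range"] = tuple(data["baseline_day_range"])
    return StudyScenario(groups=groups, **data)


def write_manifest_json(manifest: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
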