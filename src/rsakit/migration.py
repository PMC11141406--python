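"""Implant-migration computation between a baseline and a follow-up examination.

Migration is the displacement of the prosthesis relative to its host bone
since the postoperative baseline. It is computed in two steps:

1. the bone markers of the follow-up are rigidly aligned onto the bone
   markers of the baseline, removing the change in patient position
   between the two examinations; the same transform is applied to the
   follow-up prosthesis markers;
2. the rigid transform carrying the baseline prosthesis markers onto
   those repositioned follow-up markers *is* the migration.

The migration transform is decomposed, in a per-patient migration
coordinate system (origin at the geometric center of the migrating body
in the baseline, axes anatomic by default), into three signed
translations (mm), three body-fixed XYZ Euler rotations (degrees), the
summary norms TT and TR, per-point motions for markers and configured
fictive points, and MTPM — the displacement norm of the evaluated point
that moved most.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .geometry import (
    EulerAnglesXYZ,
    FitQuality,
    InsufficientMarkersError,
    RigidBodyObservation,
    RigidTransform,
    SMALL_ANGLE_LIMIT_DEG,
    euler_from_rotation,
    fit_rigid,
    rotation_from_euler,
    total_rotation,
    total_translation,
)

__all__ = [
    "Examination",
    "CoordinateSystemSpec",
    "MigrationResult",
    "compute_migration",
    "select_markers",
    "mtpm",
    "point_motion",
    "interval_migration",
    "to_right_side",
    "convert_frame",
    "RSA_TO_LPS",
]

SIDES = ("left", "right")
MODALITIES = ("RSA", "CT_RSA")
EXAM_KINDS = ("baseline", "followup", "double")

#: axis permutation RSA global (X left, Y superior, Z anterior) ->
#: DICOM LPS (X left, Y posterior, Z superior); proper rotation (det +1)
RSA_TO_LPS = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])


@dataclass
class Examination:
    """One patient/timepoint observation: marker sets plus study metadata."""

    exam_id: str
    patient_id: str
    side: str
    days_since_surgery: int
    bodies: dict[str, RigidBodyObservation]
    modality: str = "RSA"
    kind: str = "followup"
    weightbearing: str = "supine"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.kind not in EXAM_KINDS:
            raise ValueError(f"unknown exam kind {self.kind!r}")
        if self.days_since_surgery < 0:
            raise ValueError("days_since_surgery must be >= 0")


@dataclass(frozen=True)
class CoordinateSystemSpec:
    """Migration coordinate system: origin and axes.

    The default uses the geometric center (centroid) of the migrating
    body's baseline markers as origin, and axes aligned with the global
    frame (anatomic for a patient aligned with the calibration cage:
    X medial, Y superior, Z anterior for a right-sided implant). A custom
    origin (3-vector, mm) or rotation (3x3, columns = migration axes in
    global coordinates) may be supplied; the same spec must be reused
    for all follow-ups of a patient.
    """

    origin: object = "geometric_center"
    axes: object = "anatomic_default"
    anatomic_labels: tuple[str, str, str] = ("medial", "superior", "anterior")

    def axes_matrix(self) -> np.ndarray:
        if isinstance(self.axes, str):
            if self.axes != "anatomic_default":
                raise ValueError(f"unknown axes spec {self.axes!r}")
            return np.eye(3)
        A = np.asarray(self.axes, dtype=float)
        if A.shape != (3, 3) or np.max(np.abs(A.T @ A - np.eye(3))) > 1e-9:
            raise ValueError("custom axes must form a 3x3 orthonormal matrix")
        return A

    def resolve_origin(self, baseline_points: np.ndarray) -> np.ndarray:
        if isinstance(self.origin, str):
            if self.origin != "geometric_center":
                raise ValueError(f"unknown origin spec {self.origin!r}")
            return np.asarray(baseline_points, dtype=float).mean(axis=0)
        return np.asarray(self.origin, dtype=float)


@dataclass
class MigrationResult:
    """Six signed components, summary metrics, point motions and provenance."""

    patient_id: str
    baseline_exam_id: str
    followup_exam_id: str
    body_id: str
    days_since_surgery: int
    tx: float
    ty: float
    tz: float
    rx: float
    ry: float
    rz: float
    tt: float
    tr: float
    mtpm: float
    mtpm_point: str
    point_motions: dict[str, np.ndarray]
    quality_reference: FitQuality
    quality_migrating: FitQuality
    marker_method: str
    cs: CoordinateSystemSpec
    side: str
    side_convention: str = "as_measured"
    warnings: list[str] = field(default_factory=list)
    transform: RigidTransform | None = None

    @property
    def translations(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    @property
    def rotations(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz])

    def components(self) -> dict[str, float]:
        """All scalar outcomes keyed by their conventional names."""
        return {
            "tx": self.tx, "ty": self.ty, "tz": self.tz,
            "rx": self.rx, "ry": self.ry, "rz": self.rz,
            "tt": self.tt, "tr": self.tr, "mtpm": self.mtpm,
        }


def select_markers(
    baseline: Examination,
    followups: Sequence[Examination],
    method: str = "consistent",
) -> dict[str, dict[str, list[str]]]:
    """Choose which markers enter each migration computation of a series.

    ``consistent``: per body, the intersection of markers visible in the
    baseline and *every* follow-up — the same subset at all timepoints.
    ``all``: per body and per exam, the intersection with the baseline
    only, keeping markers until they disappear.

    Returns ``{body_id: {exam_id: [marker_ids]}}``.
    """
    if method not in ("consistent", "all"):
        raise ValueError(f"unknown marker method {method!r}")
    selection: dict[str, dict[str, list[str]]] = {}
    for body_id, base_body in baseline.bodies.items():
        base_ids = set(base_body.marker_ids)
        if not base_ids:
            raise ValueError(f"body {body_id!r}: baseline marker set is empty")
        per_exam: dict[str, list[str]] = {}
        if method == "consistent":
            common = set(base_ids)
            for fu in followups:
                if body_id in fu.bodies:
                    common &= set(fu.bodies[body_id].marker_ids)
            if len(common) < 3:
                raise InsufficientMarkersError(
                    f"body {body_id!r}: consistent-marker intersection has only "
                    f"{len(common)} markers; consider the all-marker method"
                )
            for fu in followups:
                per_exam[fu.exam_id] = sorted(common)
            per_exam[baseline.exam_id] = sorted(common)
        else:
            per_exam[baseline.exam_id] = sorted(base_ids)
            for fu in followups:
                if body_id in fu.bodies:
                    per_exam[fu.exam_id] = sorted(base_ids & set(fu.bodies[body_id].marker_ids))
        selection[body_id] = per_exam
    return selection


def point_motion(
    point: np.ndarray,
    transform: RigidTransform,
    axes: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Displacement of one (fictive) point under the migration transform.

    Returns the displacement vector expressed in migration axes and its
    Euclidean length (mm).
    """
    p = np.asarray(point, dtype=float)
    d = transform.apply(p) - p
    if axes is not None:
        d = np.asarray(axes, dtype=float).T @ d
    return d, float(np.linalg.norm(d))


def mtpm(
    points: Mapping[str, np.ndarray],
    transform: RigidTransform,
) -> tuple[float, str]:
    """Maximum total point motion over the evaluated point set.

    The maximum displacement norm under the migration transform, together
    with the id of the point attaining it (lexicographic tie-break).
    """
    if not points:
        raise ValueError("MTPM requires a nonempty evaluated point set")
    best_id, best_val = None, -1.0
    for pid in sorted(points):
        _, norm = point_motion(points[pid], transform)
        if norm > best_val + 1e-15:
            best_id, best_val = pid, norm
    return float(best_val), str(best_id)


def compute_migration(
    baseline: Examination,
    followup: Examination,
    reference_body: str = "bone",
    migrating_body: str = "prosthesis",
    cs: CoordinateSystemSpec | None = None,
    marker_method: str = "all",
    marker_selection: dict[str, dict[str, list[str]]] | None = None,
    fictive_points: Mapping[str, np.ndarray] | None = None,
) -> MigrationResult:
    """Compute migration of ``migrating_body`` relative to ``reference_body``.

    Implements the two-step procedure: the reference body of the
    follow-up is aligned onto the baseline reference body, that transform
    is applied to the follow-up's migrating body, and the residual rigid
    transform from the baseline migrating body onto the repositioned one
    is reported as migration in the coordinate system ``cs``.

    ``fictive_points`` (id -> 3-vector in the baseline global frame) are
    evaluated for point motion and MTPM alongside the migrating body's
    baseline markers. Quality thresholds are *not* enforced here; gating
    is a separate concern (:func:`rsakit.quality.qc_gate`).
    """
    cs = cs if cs is not None else CoordinateSystemSpec()
    for exam in (baseline, followup):
        for body in (reference_body, migrating_body):
            if body not in exam.bodies:
                raise ValueError(f"exam {exam.exam_id!r} lacks body {body!r}")

    if marker_selection is None:
        marker_selection = select_markers(baseline, [followup], method=marker_method)

    def common_ids(body_id: str) -> list[str]:
        sel = marker_selection.get(body_id, {})
        base_ids = sel.get(baseline.exam_id, baseline.bodies[body_id].marker_ids)
        fu_ids = sel.get(followup.exam_id, followup.bodies[body_id].marker_ids)
        avail = set(baseline.bodies[body_id].marker_ids) & set(followup.bodies[body_id].marker_ids)
        ids = sorted(set(base_ids) & set(fu_ids) & avail)
        if len(ids) < 3:
            raise InsufficientMarkersError(
                f"body {body_id!r}: only {len(ids)} shared markers between "
                f"{baseline.exam_id!r} and {followup.exam_id!r}"
            )
        return ids

    ref_ids = common_ids(reference_body)
    mig_ids = common_ids(migrating_body)

    base_ref = baseline.bodies[reference_body].positions(ref_ids)
    fu_ref = followup.bodies[reference_body].positions(ref_ids)
    base_mig = baseline.bodies[migrating_body].positions(mig_ids)
    fu_mig = followup.bodies[migrating_body].positions(mig_ids)

    # step 1: remove the patient-repositioning difference
    t_repos, q_ref = fit_rigid(base_ref, fu_ref)
    fu_mig_aligned = t_repos.apply(fu_mig)
    # step 2: residual motion of the migrating body is the migration
    t_mig, q_mig = fit_rigid(fu_mig_aligned, base_mig)

    origin = cs.resolve_origin(base_mig)
    A = cs.axes_matrix()
    R_mig = A.T @ t_mig.rotation @ A
    t_origin = A.T @ (t_mig.apply(origin) - origin)
    euler = euler_from_rotation(R_mig)

    warnings: list[str] = []
    if euler.gimbal_lock:
        warnings.append("gimbal lock: ry at ±90°, rz set to 0 by convention")
    tr = total_rotation(euler)
    if tr.exceeds_small_angle:
        warnings.append("total rotation exceeds the 5° small-angle validity limit")

    eval_points: dict[str, np.ndarray] = {
        mid: pos for mid, pos in zip(mig_ids, base_mig)
    }
    if fictive_points:
        for pid, pos in fictive_points.items():
            eval_points[str(pid)] = np.asarray(pos, dtype=float)
    motions = {pid: point_motion(p, t_mig, axes=A)[0] for pid, p in eval_points.items()}
    mtpm_val, mtpm_pt = mtpm(eval_points, t_mig)

    return MigrationResult(
        patient_id=baseline.patient_id,
        baseline_exam_id=baseline.exam_id,
        followup_exam_id=followup.exam_id,
        body_id=migrating_body,
        days_since_surgery=followup.days_since_surgery,
        tx=float(t_origin[0]), ty=float(t_origin[1]), tz=float(t_origin[2]),
        rx=euler.rx, ry=euler.ry, rz=euler.rz,
        tt=total_translation(t_origin),
        tr=tr.degrees,
        mtpm=mtpm_val,
        mtpm_point=mtpm_pt,
        point_motions=motions,
        quality_reference=q_ref,
        quality_migrating=q_mig,
        marker_method=marker_method,
        cs=cs,
        side=baseline.side,
        warnings=warnings,
        transform=t_mig,
    )


def interval_migration(m_early: MigrationResult, m_late: MigrationResult) -> MigrationResult:
    """Migration over the interval between two follow-ups.

    Computed by component-wise subtraction of the earlier migration from
    the later one (both relative to the same baseline), as opposed to
    re-computing with the earlier follow-up as baseline. TT/TR are
    recomputed from the differenced components and MTPM from differenced
    point-motion vectors. The subtraction is only approximate for large
    rotations; a warning flag is set when either TR exceeds 5°.
    """
    if m_early.patient_id != m_late.patient_id or m_early.body_id != m_late.body_id:
        raise ValueError("interval migration requires the same patient and body")
    if m_early.baseline_exam_id != m_late.baseline_exam_id:
        raise ValueError("interval migration requires a common baseline examination")
    if m_early.marker_method != m_late.marker_method or m_early.cs != m_late.cs:
        raise ValueError("interval migration requires identical provenance (marker method, cs)")

    dt = m_late.translations - m_early.translations
    dr = m_late.rotations - m_early.rotations
    warnings = []
    if total_rotation(m_early.rotations).exceeds_small_angle or \
            total_rotation(m_late.rotations).exceeds_small_angle:
        warnings.append("interval migration approximate for large rotations (TR > 5°)")

    common = sorted(set(m_early.point_motions) & set(m_late.point_motions))
    if common:
        diffs = {pid: m_late.point_motions[pid] - m_early.point_motions[pid] for pid in common}
        mtpm_pt = sorted(common, key=lambda pid: (-np.linalg.norm(diffs[pid]), pid))[0]
        mtpm_val = float(np.linalg.norm(diffs[mtpm_pt]))
        motions = diffs
    else:
        mtpm_val, mtpm_pt, motions = 0.0, "", {}

    tr = total_rotation(dr)
    return MigrationResult(
        patient_id=m_late.patient_id,
        baseline_exam_id=m_late.baseline_exam_id,
        followup_exam_id=f"{m_early.followup_exam_id}..{m_late.followup_exam_id}",
        body_id=m_late.body_id,
        days_since_surgery=m_late.days_since_surgery,
        tx=float(dt[0]), ty=float(dt[1]), tz=float(dt[2]),
        rx=float(dr[0]), ry=float(dr[1]), rz=float(dr[2]),
        tt=total_translation(dt),
        tr=tr.degrees,
        mtpm=mtpm_val,
        mtpm_point=mtpm_pt,
        point_motions=motions,
        quality_reference=m_late.quality_reference,
        quality_migrating=m_late.quality_migrating,
        marker_method=m_late.marker_method,
        cs=m_late.cs,
        side=m_late.side,
        side_convention=m_late.side_convention,
        warnings=warnings,
        transform=None,
    )


def to_right_side(result: MigrationResult, side: str | None = None) -> MigrationResult:
    """Convert a left-sided result to the right-side convention.

    For left-sided prostheses, translations along X and rotations about Y
    and Z change sign when mirrored onto the right side; the norms (TT,
    TR, MTPM) are unchanged. Right-sided results pass through untouched.
    Applying the conversion twice restores the original values.
    """
    side = side if side is not None else result.side
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    if side == "right":
        return result
    flipped = {pid: v * np.array([-1.0, 1.0, 1.0]) for pid, v in result.point_motions.items()}
    converted = "converted_to_right" if result.side_convention == "as_measured" else "as_measured"
    return replace(
        result,
        tx=-result.tx,
        ry=-result.ry,
        rz=-result.rz,
        point_motions=flipped,
        side_convention=converted,
    )


def convert_frame(value, from_frame: str, to_frame: str):
    """Map a 3-vector or :class:`RigidTransform` between RSA and LPS frames.

    RSA global: X left, Y superior, Z anterior. DICOM LPS: X left,
    Y posterior, Z superior. The mapping is the fixed proper axis
    permutation sharing the left axis; the round trip is the identity.
    """
    frames = {"RSA_GLOBAL", "DICOM_LPS"}
    if from_frame not in frames or to_frame not in frames:
        raise ValueError(f"unknown frame tag {from_frame!r} or {to_frame!r}")
    if from_frame == to_frame:
        raise ValueError("frames must differ")
    M = RSA_TO_LPS if from_frame == "RSA_GLOBAL" else RSA_TO_LPS.T
    if isinstance(value, RigidTransform):
        return RigidTransform(M @ value.rotation @ M.T, M @ value.translation)
    v = np.asarray(value, dtype=float)
    if v.shape != (3,):
        raise ValueError("expected a 3-vector or RigidTransform")
    return M @ v
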