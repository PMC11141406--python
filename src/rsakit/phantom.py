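"""Synthetic RSA setups, phantom experiments and longitudinal studies.

Everything the toolkit consumes can be generated here: calibration cages
with a plausible two-layer fiducial/control layout, noisy stereo
projections with occlusion, micro-manipulator phantom runs whose applied
poses are exact by construction (and therefore trivially satisfy the
"gold standard an order of magnitude better" requirement), and full
longitudinal migration studies with repositioning, marker instability,
double examinations and dropout.

All randomness flows from a single seed; identical seeds give identical
outputs byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calibration import (
    CalibrationCage,
    ImageDetections,
    ProjectionGeometry,
    calibrate_image,
    reconstruct_markers,
)
from .geometry import (
    MarkerObservation,
    RigidBodyObservation,
    RigidTransform,
    condition_number,
    rotation_from_euler,
    euler_from_rotation,
    total_rotation,
    total_translation,
)
from .migration import CoordinateSystemSpec, Examination, compute_migration, mtpm
from .quality import accuracy_vs_gold

__all__ = [
    "SyntheticSetup",
    "make_setup",
    "gen_marker_config",
    "project_markers",
    "PhantomProtocol",
    "run_phantom_experiment",
    "StudyGroup",
    "StudyScenario",
    "StudyData",
    "gen_study",
]


# --------------------------------------------------------------------------
# synthetic radiographic setup


@dataclass
class _PlaneSpec:
    origin: np.ndarray
    axes: np.ndarray  # (3, 2)

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.axes[:, 0], self.axes[:, 1])


@dataclass
class _DetectorFrame:
    """In-plane similarity between cage plane coordinates and detector uv."""

    angle_deg: float
    offset: np.ndarray

    def to_detector(self, st: np.ndarray) -> np.ndarray:
        a = math.radians(self.angle_deg)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        return R @ st + self.offset


@dataclass
class SyntheticSetup:
    """Ground-truth stereo geometry: cage, true foci and detector frames."""

    cage: CalibrationCage
    planes: dict[str, _PlaneSpec]
    foci: dict[str, np.ndarray]
    detector_frames: dict[str, _DetectorFrame]
    image_marker_sets: dict[str, set[str]]  # cage marker ids visible per image
    marker_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def project(self, point: np.ndarray, image_id: str) -> np.ndarray:
        """True central projection of a 3D point onto one detector (uv, mm)."""
        focus = self.foci[image_id]
        plane = self.planes[image_id]
        d = np.asarray(point, dtype=float) - focus
        denom = d @ plane.normal
        if abs(denom) < 1e-12:
            raise ValueError("ray parallel to the image plane")
        s = ((plane.origin - focus) @ plane.normal) / denom
        if s < 1.0 - 1e-9:
            raise ValueError("point behind focus or beyond the image plane")
        hit = focus + s * d
        st = plane.axes.T @ (hit - plane.origin)
        return self.detector_frames[image_id].to_detector(st)


def _uniplanar_setup(beam_angle_deg: float = 40.0) -> SyntheticSetup:
    """Side-by-side detectors in one plane, foci at 1 m, beams at ~40°."""
    plane = _PlaneSpec(np.zeros(3), np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]))
    h = 1000.0
    half = math.tan(math.radians(beam_angle_deg / 2.0)) * h
    foci = {"A": np.array([-half, 0.0, h]), "B": np.array([half, 0.0, h])}
    fiducials: dict[str, np.ndarray] = {}
    controls: dict[str, np.ndarray] = {}
    image_sets: dict[str, set[str]] = {"A": set(), "B": set()}
    for img, sign in (("A", 1.0), ("B", -1.0)):
        # fiducial grid in the detector-plane layer of this image's half
        k = 0
        for x in (40.0, 130.0, 220.0):
            for y in (-90.0, 0.0, 90.0):
                mid = f"f{img}{k}"
                fiducials[mid] = np.array([sign * x, y, 0.0])
                image_sets[img].add(mid)
                k += 1
        # control markers in a layer between plane and focus, placed on
        # rays from this image's focus toward points inside its region
        focus = foci[img]
        k = 0
        for target in (
            np.array([sign * 70.0, -50.0, 0.0]),
            np.array([sign * 70.0, 50.0, 0.0]),
            np.array([sign * 190.0, -50.0, 0.0]),
            np.array([sign * 190.0, 50.0, 0.0]),
        ):
            for height in (250.0, 330.0):
                frac = (h - height) / h
                pos = focus + frac * (target - focus)
                mid = f"c{img}{k}"
                controls[mid] = pos
                image_sets[img].add(mid)
                k += 1
    cage = CalibrationCage("uniplanar", fiducials, controls, beam_angle_deg)
    frames = {
        "A": _DetectorFrame(2.5, np.array([-120.0, 6.0])),
        "B": _DetectorFrame(-1.5, np.array([115.0, -8.0])),
    }
    return SyntheticSetup(
        cage=cage,
        planes={"A": plane, "B": plane},
        foci=foci,
        detector_frames=frames,
        image_marker_sets=image_sets,
        marker_center=np.array([0.0, 0.0, 190.0]),
    )


def _biplanar_setup() -> SyntheticSetup:
    """Perpendicular detector planes, beams crossing at ~90°."""
    plane_a = _PlaneSpec(np.zeros(3), np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]))
    plane_b = _PlaneSpec(
        np.array([350.0, 0.0, 150.0]),
        np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
    )
    foci = {"A": np.array([0.0, 0.0, 1000.0]), "B": np.array([-650.0, 0.0, 150.0])}
    fiducials: dict[str, np.ndarray] = {}
    controls: dict[str, np.ndarray] = {}
    image_sets: dict[str, set[str]] = {"A": set(), "B": set()}
    k = 0
    for x in (-90.0, 0.0, 90.0):
        for y in (-90.0, 0.0, 90.0):
            mid = f"fA{k}"
            fiducials[mid] = np.array([x, y, 0.0])
            image_sets["A"].add(mid)
            k += 1
    k = 0
    for y in (-90.0, 0.0, 90.0):
        for z in (60.0, 150.0, 240.0):
            mid = f"fB{k}"
            fiducials[mid] = np.array([350.0, y, z])
            image_sets["B"].add(mid)
            k += 1
    k = 0
    for target in (
        np.array([-50.0, -50.0, 0.0]),
        np.array([-50.0, 50.0, 0.0]),
        np.array([50.0, -50.0, 0.0]),
        np.array([50.0, 50.0, 0.0]),
    ):
        for height in (250.0, 330.0):
            frac = (1000.0 - height) / 1000.0
            controls[f"cA{k}"] = foci["A"] + frac * (target - foci["A"])
            image_sets["A"].add(f"cA{k}")
            k += 1
    k = 0
    for target in (
        np.array([350.0, -50.0, 100.0]),
        np.array([350.0, 50.0, 100.0]),
        np.array([350.0, -50.0, 200.0]),
        np.array([350.0, 50.0, 200.0]),
    ):
        for depth in (150.0, 230.0):
            frac = (1000.0 - depth) / 1000.0
            controls[f"cB{k}"] = foci["B"] + frac * (target - foci["B"])
            image_sets["B"].add(f"cB{k}")
            k += 1
    cage = CalibrationCage("biplanar", fiducials, controls, 90.0)
    frames = {
        "A": _DetectorFrame(1.0, np.array([4.0, -3.0])),
        "B": _DetectorFrame(-2.0, np.array([-6.0, 5.0])),
    }
    return SyntheticSetup(
        cage=cage,
        planes={"A": plane_a, "B": plane_b},
        foci=foci,
        detector_frames=frames,
        image_marker_sets=image_sets,
        marker_center=np.array([0.0, 0.0, 160.0]),
    )


def make_setup(cage_type: str = "uniplanar", beam_angle_deg: float | None = None) -> SyntheticSetup:
    """Build the synthetic radiographic setup for a cage type.

    The cage layout (two-layer fiducial/control geometry, focus height
    1 m) is a plausible standard cage; the real cages in use vary and
    their exact layouts are proprietary.
    """
    if cage_type == "uniplanar":
        return _uniplanar_setup(40.0 if beam_angle_deg is None else beam_angle_deg)
    if cage_type == "biplanar":
        if beam_angle_deg not in (None, 90.0):
            raise ValueError("biplanar setup is fixed at 90°")
        return _biplanar_setup()
    raise ValueError(f"unknown cage type {cage_type!r}")


# --------------------------------------------------------------------------
# marker configurations and projections


def gen_marker_config(
    n: int,
    spread_mm: float = 30.0,
    collinearity: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample a marker configuration inside an ellipsoid.

    ``collinearity`` in [0, 1] shrinks two semi-axes toward zero, driving
    the condition number up monotonically; 0 gives a well-dispersed
    (roughly spherical) cloud as recommended for bone marking, 1 gives an
    exactly collinear set.
    """
    if n < 3:
        raise ValueError("a rigid body needs at least 3 markers")
    if not (0.0 <= collinearity <= 1.0):
        raise ValueError("collinearity must be in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    # uniform in the unit ball, then scaled by the ellipsoid semi-axes
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * n, 3))
        keep = cand[np.linalg.norm(cand, axis=1) <= 1.0]
        take = min(len(keep), n - got)
        pts[got:got + take] = keep[:take]
        got += take
    semi = np.array([1.0, 1.0 - collinearity, 1.0 - collinearity]) * spread_mm
    config = pts * semi
    if collinearity < 1.0 and not np.isfinite(condition_number(config)):
        # astronomically unlikely for random samples, but keep the contract
        return gen_marker_config(n, spread_mm, collinearity, rng)
    return config


def project_markers(
    points: Mapping[str, np.ndarray],
    setup: SyntheticSetup,
    image_id: str,
    noise_sd: float = 0.0,
    occlusion_prob: float = 0.0,
    rng: np.random.Generator | int | None = None,
    include_cage: bool = True,
    dpi: float = 150.0,
    bit_depth: int = 8,
) -> ImageDetections:
    """Project labeled 3D points onto one detector.

    Central projection through the true focus, additive isotropic 2D
    Gaussian noise, and Bernoulli occlusion dropping markers per image.
    Cage markers visible in this image are included (with the same noise)
    unless ``include_cage`` is false.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    detections: dict[str, np.ndarray] = {}
    all_points: dict[str, np.ndarray] = {}
    if include_cage:
        for mid in sorted(setup.image_marker_sets[image_id]):
            pos = setup.cage.fiducials.get(mid)
            if pos is None:
                pos = setup.cage.controls[mid]
            all_points[mid] = pos
    for mid in sorted(points):
        all_points[mid] = np.asarray(points[mid], dtype=float)
    for mid, pos in all_points.items():
        is_cage = include_cage and mid in setup.image_marker_sets[image_id]
        if not is_cage and occlusion_prob > 0.0 and rng.random() < occlusion_prob:
            continue
        uv = setup.project(pos, image_id)
        if noise_sd > 0.0:
            uv = uv + rng.normal(0.0, noise_sd, size=2)
        detections[mid] = uv
    return ImageDetections(image_id=image_id, points=detections, dpi=dpi, bit_depth=bit_depth)


def _reconstruct_exam(
    setup: SyntheticSetup,
    bodies_points: Mapping[str, Mapping[str, np.ndarray]],
    exam_id: str,
    patient_id: str,
    side: str,
    days: int,
    kind: str,
    noise_sd: float,
    occlusion_prob: float,
    rng: np.random.Generator,
) -> Examination:
    """Project all bodies into both images, calibrate and triangulate."""
    flat: dict[str, np.ndarray] = {}
    owner: dict[str, str] = {}
    for body_id, pts in bodies_points.items():
        for mid, pos in pts.items():
            key = f"{body_id}:{mid}"
            flat[key] = pos
            owner[key] = body_id
    geoms: dict[str, ProjectionGeometry] = {}
    dets: dict[str, ImageDetections] = {}
    for image_id in ("A", "B"):
        det = project_markers(
            flat, setup, image_id, noise_sd=noise_sd,
            occlusion_prob=occlusion_prob, rng=rng,
        )
        dets[image_id] = det
        geoms[image_id] = calibrate_image(setup.cage, det)
    recon = reconstruct_markers(
        geoms["A"], geoms["B"], dets["A"], dets["B"], marker_ids=sorted(flat)
    )
    bodies: dict[str, RigidBodyObservation] = {}
    for body_id in bodies_points:
        markers = [
            MarkerObservation(
                key.split(":", 1)[1], recon.positions[key],
                role="prosthesis" if body_id == "prosthesis" else "bone",
            )
            for key in sorted(recon.positions)
            if owner.get(key) == body_id
        ]
        bodies[body_id] = RigidBodyObservation(body_id, markers, frame="RSA_GLOBAL")
    return Examination(
        exam_id=exam_id, patient_id=patient_id, side=side,
        days_since_surgery=days, bodies=bodies, kind=kind,
        metadata={"dpi": 150.0, "bit_depth": 8},
    )


# --------------------------------------------------------------------------
# phantom accuracy experiment


@dataclass
class PhantomProtocol:
    """Micro-manipulator phantom protocol: exact applied poses.

    ``poses`` is the grid of (translation mm, rotation deg) applied to
    the migrating body relative to the reference body; the applied values
    are exact by construction, so the gold standard is arbitrarily better
    than the assessed method.
    """

    poses: Sequence[tuple[np.ndarray, np.ndarray]]
    noise_sd_mm: float = 0.05
    replicates: int = 10
    cage_type: str = "uniplanar"
    prosthesis_scale: float = 1.0
    seed: int = 0

    @classmethod
    def default_grid(cls, **kwargs) -> "PhantomProtocol":
        """Translations and rotations about each of the three axes."""
        poses = []
        for axis in range(3):
            t = np.zeros(3)
            t[axis] = 0.5
            poses.append((t, np.zeros(3)))
            r = np.zeros(3)
            r[axis] = 1.0
            poses.append((np.zeros(3), r))
        poses.append((np.array([0.2, -0.3, 0.4]), np.array([0.5, -0.4, 0.6])))
        return cls(poses=poses, **kwargs)


def run_phantom_experiment(protocol: PhantomProtocol) -> "pd.DataFrame":
    """Simulate a phantom accuracy experiment end to end.

    For every pose and replicate, a baseline and a moved examination are
    projected through the full synthetic stereo chain (cage detections
    with noise, calibration, triangulation), migration is computed, and
    the measured outcomes are compared against the exactly known applied
    poses with :func:`rsakit.quality.accuracy_vs_gold`.
    """
    import pandas as pd  # deferred; keeps module import light

    rng = np.random.default_rng(protocol.seed)
    setup = make_setup(protocol.cage_type)
    center = setup.marker_center
    bone_pts = gen_marker_config(6, spread_mm=45.0, rng=rng) + center
    pros_local = gen_marker_config(4, spread_mm=25.0, rng=rng) * protocol.prosthesis_scale
    pros_pts = pros_local + center + np.array([0.0, 0.0, 25.0])
    pros_centroid = pros_pts.mean(axis=0)

    bone = {f"b{i}": p for i, p in enumerate(bone_pts)}
    measured_rows: list[dict[str, float]] = []
    truth_rows: list[dict[str, float]] = []
    for translation, rotation_deg in protocol.poses:
        R = rotation_from_euler(np.asarray(rotation_deg, dtype=float))
        t_vec = np.asarray(translation, dtype=float)
        moved = (pros_pts - pros_centroid) @ R.T + pros_centroid + t_vec
        truth_transform = RigidTransform(R, pros_centroid - R @ pros_centroid + t_vec)
        truth_points = {f"p{i}": p for i, p in enumerate(pros_pts)}
        mtpm_true, _ = mtpm(truth_points, truth_transform)
        euler_true = euler_from_rotation(R)
        truth = {
            "tx": float(t_vec[0]), "ty": float(t_vec[1]), "tz": float(t_vec[2]),
            "rx": euler_true.rx, "ry": euler_true.ry, "rz": euler_true.rz,
            "tt": total_translation(t_vec),
            "tr": total_rotation(euler_true).degrees,
            "mtpm": mtpm_true,
        }
        pros_moved = {f"p{i}": p for i, p in enumerate(moved)}
        pros_base = {f"p{i}": p for i, p in enumerate(pros_pts)}
        for _ in range(protocol.replicates):
            base_exam = _reconstruct_exam(
                setup, {"bone": bone, "prosthesis": pros_base},
                "base", "phantom", "right", 0, "baseline",
                protocol.noise_sd_mm, 0.0, rng,
            )
            fu_exam = _reconstruct_exam(
                setup, {"bone": bone, "prosthesis": pros_moved},
                "fu", "phantom", "right", 0, "followup",
                protocol.noise_sd_mm, 0.0, rng,
            )
            res = compute_migration(base_exam, fu_exam)
            measured_rows.append(res.components())
            truth_rows.append(truth)
    table = accuracy_vs_gold(measured_rows, truth_rows)
    mdf = pd.DataFrame(measured_rows)
    table.attrs["measured_mean"] = {k: float(mdf[k].mean()) for k in mdf.columns}
    table.attrs["truth_mean"] = {
        k: float(np.mean([t[k] for t in truth_rows])) for k in truth_rows[0]
    }
    return table


# --------------------------------------------------------------------------
# longitudinal study generation


@dataclass
class StudyGroup:
    """One treatment arm of a simulated migration study."""

    name: str
    n_patients: int
    migration_model: str = "plateau"  # "plateau" | "continuous"
    magnitude_mm: float = 0.6  # plateau asymptote, or rate per year for "continuous"
    rotation_deg: float = 0.5  # rotation magnitude paired with the translation course
    noise_sd_mm: float = 0.05  # per-component 3D measurement noise
    fraction_left: float = 0.5

    def __post_init__(self) -> None:
        if self.migration_model not in ("plateau", "continuous"):
            raise ValueError(f"unknown migration model {self.migration_model!r}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass
class StudyScenario:
    """Full scenario for :func:`gen_study`.

    Timepoints default to the recommended schedule (6 weeks, 3, 6, 12 and
    24 months); at least 25% of patients receive a same-day double
    examination at the first follow-up.
    """

    groups: Sequence[StudyGroup]
    timepoints_days: Sequence[int] = (42, 91, 182, 365, 730)
    double_fraction: float = 0.25
    occlusion_prob: float = 0.0
    instability_sd_mm: float = 0.0
    dropout_hazard: float = 0.0  # per-timepoint probability of leaving the study
    baseline_day_range: tuple[int, int] = (2, 10)
    plateau_tau_days: float = 90.0
    seed: int = 0


@dataclass
class StudyData:
    """Generated study: manifest, examinations and hidden ground truth."""

    manifest: dict
    examinations: list[Examination]
    truth: dict  # patient_id -> {timepoint_days: {outcome: value}}


def _random_rigid(rng: np.random.Generator, max_rot_deg: float, max_trans_mm: float) -> RigidTransform:
    angles = rng.uniform(-max_rot_deg, max_rot_deg, size=3)
    trans = rng.uniform(-max_trans_mm, max_trans_mm, size=3)
    return RigidTransform(rotation_from_euler(angles), trans)


def _migration_magnitude(model: str, t_days: float, magnitude: float, tau: float) -> float:
    if model == "plateau":
        return magnitude * (1.0 - math.exp(-t_days / tau))
    return magnitude * t_days / 365.0


def gen_study(scenario: StudyScenario) -> StudyData:
    """Generate a longitudinal migration study with known ground truth.

    Per patient: a baseline within two weeks of surgery and follow-ups at
    the protocol timepoints; the prosthesis migrates along a fixed
    patient-specific direction (and rotates about a fixed axis) following
    the group's trajectory model. Patient repositioning between exams,
    per-component measurement noise, optional cumulative marker drift,
    occlusion and dropout are applied. True migration components are
    stored separately for recovery tests.

    Measurement noise is applied directly to the 3D marker coordinates;
    the full projection chain is exercised by the phantom experiment.
    """
    rng = np.random.default_rng(scenario.seed)
    exams: list[Examination] = []
    truth: dict[str, dict[int, dict[str, float]]] = {}
    patients = []
    doubles: list[str] = []
    missing: dict[str, dict[int, str]] = {}

    for group in scenario.groups:
        n_doubles = math.ceil(scenario.double_fraction * group.n_patients)
        for i in range(group.n_patients):
            pid = f"{group.name}-{i:03d}"
            side = "left" if rng.random() < group.fraction_left else "right"
            baseline_day = int(rng.integers(*scenario.baseline_day_range, endpoint=True))
            patients.append({
                "patient_id": pid, "group": group.name, "side": side,
                "baseline_day": baseline_day,
            })
            bone_local = gen_marker_config(6, spread_mm=45.0, rng=rng)
            pros_local = gen_marker_config(4, spread_mm=25.0, rng=rng)
            pros_offset = np.array([0.0, 0.0, 40.0])
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            rot_axis_angles = rng.normal(size=3)
            rot_axis_angles /= np.linalg.norm(rot_axis_angles)
            drift = np.zeros((len(bone_local) + len(pros_local), 3))

            dropout_after: int | None = None
            if scenario.dropout_hazard > 0.0:
                for k in range(len(scenario.timepoints_days)):
                    if rng.random() < scenario.dropout_hazard:
                        dropout_after = k
                        break

            def build_exam(exam_id: str, day: int, kind: str, mig: RigidTransform) -> Examination:
                # the patient is aligned with the calibration cage at baseline,
                # so the baseline exam defines the (anatomic) migration frame;
                # follow-ups carry a random repositioning
                if kind == "baseline":
                    repos = RigidTransform.identity()
                else:
                    repos = _random_rigid(rng, max_rot_deg=5.0, max_trans_mm=15.0)
                bone_pts = bone_local.copy()
                pros_pts = mig.apply(pros_local + pros_offset)
                all_pts = np.vstack([bone_pts, pros_pts]) + drift
                all_pts = repos.apply(all_pts)
                all_pts = all_pts + rng.normal(0.0, group.noise_sd_mm, size=all_pts.shape)
                nb = len(bone_local)
                bone_markers = [
                    MarkerObservation(f"b{j}", all_pts[j], role="bone") for j in range(nb)
                ]
                pros_markers = [
                    MarkerObservation(f"p{j}", all_pts[nb + j], role="prosthesis")
                    for j in range(len(pros_local))
                ]
                if scenario.occlusion_prob > 0.0 and kind != "baseline":
                    kept_b = [m for m in bone_markers if rng.random() >= scenario.occlusion_prob]
                    kept_p = [m for m in pros_markers if rng.random() >= scenario.occlusion_prob]
                    if len(kept_b) >= 3:
                        bone_markers = kept_b
                    if len(kept_p) >= 3:
                        pros_markers = kept_p
                return Examination(
                    exam_id=exam_id, patient_id=pid, side=side, days_since_surgery=day,
                    bodies={
                        "bone": RigidBodyObservation("bone", bone_markers),
                        "prosthesis": RigidBodyObservation("prosthesis", pros_markers),
                    },
                    kind=kind,
                    metadata={"dpi": 150.0, "bit_depth": 8, "group": group.name},
                )

            exams.append(build_exam(f"{pid}-base", baseline_day, "baseline", RigidTransform.identity()))
            truth[pid] = {}
            missing[pid] = {}
            pros_centroid = (pros_local + pros_offset).mean(axis=0)
            for k, tp in enumerate(scenario.timepoints_days):
                if dropout_after is not None and k >= dropout_after:
                    missing[pid][int(tp)] = "dropout"
                    continue
                if scenario.instability_sd_mm > 0.0:
                    drift += rng.normal(0.0, scenario.instability_sd_mm, size=drift.shape)
                m = _migration_magnitude(
                    group.migration_model, float(tp), group.magnitude_mm, scenario.plateau_tau_days
                )
                rot_frac = m / max(group.magnitude_mm, 1e-12) if group.migration_model == "plateau" \
                    else float(tp) / 365.0
                angles = rot_axis_angles * group.rotation_deg * rot_frac
                R = rotation_from_euler(angles)
                t_vec = direction * m
                mig = RigidTransform(R, pros_centroid - R @ pros_centroid + t_vec)
                day = max(int(tp + round(rng.normal(0.0, 3.0))), baseline_day + 1)
                exams.append(build_exam(f"{pid}-t{tp}", day, "followup", mig))
                if k == 0 and i < n_doubles:
                    # same-day repeat with repositioning: the double examination
                    doubles.append(pid)
                    exams.append(build_exam(f"{pid}-t{tp}-double", day, "double", mig))
                euler = euler_from_rotation(R)
                pts = {f"p{j}": p for j, p in enumerate(pros_local + pros_offset)}
                mtpm_true, _ = mtpm(pts, mig)
                truth[pid][int(tp)] = {
                    "tx": float(t_vec[0]), "ty": float(t_vec[1]), "tz": float(t_vec[2]),
                    "rx": euler.rx, "ry": euler.ry, "rz": euler.rz,
                    "tt": total_translation(t_vec),
                    "tr": total_rotation(euler).degrees,
                    "mtpm": mtpm_true,
                }
    manifest = {
        "groups": [
            {"name": g.name, "n_patients": g.n_patients, "migration_model": g.migration_model}
            for g in scenario.groups
        ],
        "patients": patients,
        "timepoints_days": list(int(t) for t in scenario.timepoints_days),
        "double_exam_patients": doubles,
        "double_fraction": scenario.double_fraction,
        "missing": {pid: m for pid, m in missing.items() if m},
        "seed": scenario.seed,
        "modality": "RSA",
    }
    return StudyData(manifest=manifest, examinations=exams, truth=truth)
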