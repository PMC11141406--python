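"""Rigid-body registration and kinematic primitives for RSA migration analysis.

The quantities here are the internal-validation metrics and motion
decompositions used throughout marker-based radiostereometry:

* least-squares rigid superposition of two corresponding marker sets
  (the "rigid-body fitting" step of every migration computation),
* the mean error of rigid-body fitting (ME) — the RMS residual after
  optimal superposition, a gauge of marker stability over time,
* the condition number (CN) of a marker configuration — a collinearity
  gauge from the singular values of the centered position matrix,
* Euler decomposition of rotations in the body-fixed XYZ sequence, and
* the total-translation / total-rotation summary norms.

All positions are in millimetres, all angles in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "MarkerObservation",
    "RigidBodyObservation",
    "RigidTransform",
    "FitQuality",
    "EulerAnglesXYZ",
    "TotalRotation",
    "fit_rigid",
    "mean_error",
    "condition_number",
    "euler_from_rotation",
    "rotation_from_euler",
    "total_translation",
    "total_rotation",
    "DegenerateConfigurationError",
    "InsufficientMarkersError",
]

#: singular-value ratio below which a configuration is treated as collinear
DEGENERACY_TOL = 1e-9
#: orthonormality tolerance for rotation matrices
ORTHONORMALITY_TOL = 1e-9

MARKER_ROLES = frozenset({"bone", "prosthesis", "fictive", "cage_fiducial", "cage_control"})
FRAMES = frozenset({"RSA_GLOBAL", "DICOM_LPS", "MIGRATION"})


class InsufficientMarkersError(ValueError):
    """Raised when fewer than 3 corresponding markers are available."""


class DegenerateConfigurationError(ValueError):
    """Raised when a marker configuration is (numerically) collinear."""


@dataclass(frozen=True)
class MarkerObservation:
    """One observed marker: identity, 3D position (mm) and its role."""

    marker_id: str
    position: np.ndarray
    role: str = "bone"
    diameter_mm: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"marker {self.marker_id!r}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.role not in MARKER_ROLES:
            raise ValueError(f"unknown marker role {self.role!r}")


@dataclass
class RigidBodyObservation:
    """The markers of one rigid body (bone or prosthesis) in one examination."""

    body_id: str
    markers: Sequence[MarkerObservation]
    frame: str = "RSA_GLOBAL"

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"unknown frame {self.frame!r}")
        ids = [m.marker_id for m in self.markers]
        if len(ids) != len(set(ids)):
            raise ValueError(f"body {self.body_id!r}: duplicate marker ids")

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def positions(self, marker_ids: Sequence[str] | None = None) -> np.ndarray:
        """Positions as an (n, 3) array, optionally restricted/ordered by id."""
        if marker_ids is None:
            return np.array([m.position for m in self.markers], dtype=float)
        by_id = {m.marker_id: m.position for m in self.markers}
        return np.array([by_id[i] for i in marker_ids], dtype=float)

    def subset(self, marker_ids: Sequence[str]) -> "RigidBodyObservation":
        keep = set(marker_ids)
        return RigidBodyObservation(
            body_id=self.body_id,
            markers=[m for m in self.markers if m.marker_id in keep],
            frame=self.frame,
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: x ↦ R·x + t with R orthonormal, det(R) = +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6:
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid motions (det must be +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to a 3-vector or an (n, 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass(frozen=True)
class FitQuality:
    """Quality of one rigid-body fit: ME (mm), CN and the marker count."""

    me: float
    cn: float
    n_markers: int


@dataclass(frozen=True)
class EulerAnglesXYZ:
    """Body-fixed (intrinsic) XYZ Euler angles in degrees."""

    rx: float
    ry: float
    rz: float
    gimbal_lock: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz], dtype=float)


@dataclass(frozen=True)
class TotalRotation:
    """Euclidean norm of the three Euler components, with the small-angle caveat.

    The Pythagorean summary of rotations is only meaningful for small
    (< 5°) rotations; ``exceeds_small_angle`` is set when any component
    magnitude or the norm itself exceeds that limit.
    """

    degrees: float
    exceeds_small_angle: bool


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in point set")
    return pts


def condition_number(
    points: np.ndarray, scaling: str = "dimensionless"
) -> float:
    """Condition number of a marker configuration.

    Computed from the singular values σ1 ≥ σ2 ≥ σ3 of the matrix of
    centroid-centered positions as σ1/σ3. High values flag marker sets
    that are close to collinear and therefore poorly constrain rotation.
    An exactly (or numerically, σ3/σ1 < 1e-9) collinear set yields ``inf``.

    Parameters
    ----------
    points : (n, 3) array, n ≥ 3
    scaling : {"dimensionless", "per_mm"}
        "dimensionless" returns σ1/σ3 directly; "per_mm" divides by the
        configuration half-extent (max distance from centroid), yielding a
        1/mm quantity. The choice of scale for the customary cut-off of
        120 is a convention of the analysis software; both are offered.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise InsufficientMarkersError("condition number requires at least 3 points")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0.0 or sv[2] / sv[0] < DEGENERACY_TOL:
        return float("inf")
    cn = float(sv[0] / sv[2])
    if scaling == "dimensionless":
        return cn
    if scaling == "per_mm":
        half_extent = float(np.max(np.linalg.norm(centered, axis=1)))
        return cn / half_extent
    raise ValueError(f"unknown CN scaling mode {scaling!r}")


def is_collinear(points: np.ndarray) -> bool:
    """True when the configuration is numerically collinear (σ2/σ1 ≈ 0).

    Collinearity — not mere planarity — is the degeneracy that makes
    rigid-body fitting ill-posed: a planar set (e.g. any 3 non-collinear
    markers) still determines the rotation.
    """
    pts = _as_points(points)
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    return bool(sv[0] == 0.0 or sv[1] / sv[0] < DEGENERACY_TOL)


def fit_rigid(
    reference: np.ndarray,
    moving: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, FitQuality]:
    """Least-squares rigid superposition: find T with T(moving) ≈ reference.

    The rotation is obtained from the SVD of the weighted cross-covariance
    of the centered point sets, with the smallest-singular-value sign
    correction so that only proper rotations (det = +1) are returned.
    The returned :class:`FitQuality` carries the ME (RMS residual after
    superposition, mm) and the CN of the *reference* configuration.

    Parameters
    ----------
    reference, moving : (n, 3) arrays with row-wise correspondence, n ≥ 3
    weights : optional per-marker non-negative weights (default uniform)
    """
    ref = _as_points(reference)
    mov = _as_points(moving)
    if ref.shape != mov.shape:
        raise ValueError("reference and moving sets must have the same shape")
    n = len(ref)
    if n < 3:
        raise InsufficientMarkersError(
            f"insufficient markers: rigid fit needs >= 3 correspondences, got {n}"
        )
    if is_collinear(ref):
        raise DegenerateConfigurationError(
            "degenerate configuration: reference markers are collinear (CN = inf)"
        )
    # CN is infinite for exactly planar sets under the σ1/σ3 definition;
    # the fit itself only requires non-collinearity
    cn = condition_number(ref)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    c_ref = w @ ref
    c_mov = w @ mov
    # cross-covariance H maps moving-centered onto reference-centered
    H = (mov - c_mov).T @ ((ref - c_ref) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = c_ref - R @ c_mov
    transform = RigidTransform(R, t)
    me = mean_error(ref, mov, transform)
    return transform, FitQuality(me=me, cn=cn, n_markers=n)


def mean_error(
    reference: np.ndarray, moving: np.ndarray, transform: RigidTransform
) -> float:
    """ME: RMS of residual marker distances after applying ``transform``.

    sqrt(mean_i ||T(moving_i) − reference_i||²), in mm.
    """
    ref = _as_points(reference)
    mov = _as_points(moving)
    if ref.shape != mov.shape or len(ref) == 0:
        raise ValueError("reference and moving must be equal-length, nonempty sets")
    residuals = transform.apply(mov) - ref
    return float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6 or np.linalg.det(R) < 0:
        raise ValueError("input is not a proper orthonormal rotation matrix")
    return R


def euler_from_rotation(rotation: np.ndarray) -> EulerAnglesXYZ:
    """Decompose a rotation matrix into body-fixed XYZ Euler angles (degrees).

    Near gimbal lock (ry = ±90°) the decomposition is not unique; the
    convention rz = 0 is returned and the ``gimbal_lock`` flag is set.
    """
    R = _check_rotation(rotation)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rx, ry, rz = Rotation.from_matrix(R).as_euler("XYZ", degrees=True)
    gimbal = any("imbal" in str(c.message) for c in caught)
    return EulerAnglesXYZ(float(rx), float(ry), float(rz), gimbal_lock=gimbal)


def rotation_from_euler(euler: EulerAnglesXYZ | Sequence[float]) -> np.ndarray:
    """Rotation matrix from body-fixed XYZ Euler angles in degrees."""
    if isinstance(euler, EulerAnglesXYZ):
        angles = euler.as_array()
    else:
        angles = np.asarray(euler, dtype=float)
    return Rotation.from_euler("XYZ", angles, degrees=True).as_matrix()


def total_translation(translation: np.ndarray) -> float:
    """TT: Euclidean length of the translation vector, mm."""
    t = np.asarray(translation, dtype=float)
    return float(np.linalg.norm(t))


SMALL_ANGLE_LIMIT_DEG = 5.0


def total_rotation(euler: EulerAnglesXYZ | Sequence[float]) -> TotalRotation:
    """TR: Euclidean norm of the three Euler components, degrees.

    The norm is only a valid rotation summary for small rotations; the
    result is flagged when any component or the norm exceeds 5°.
    """
    if isinstance(euler, EulerAnglesXYZ):
        angles = euler.as_array()
    else:
        angles = np.asarray(euler, dtype=float)
    norm = float(np.linalg.norm(angles))
    exceeded = bool(norm > SMALL_ANGLE_LIMIT_DEG or np.any(np.abs(angles) > SMALL_ANGLE_LIMIT_DEG))
    return TotalRotation(degrees=norm, exceeds_small_angle=exceeded)
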