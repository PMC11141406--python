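"""Calibration-cage based stereo calibration and 3D marker reconstruction.

An RSA examination consists of two simultaneous roentgen projections of
the patient together with a calibration cage. The cage carries two kinds
of markers at known positions in its own (= RSA global) frame:

* *fiducial* markers lying in the detector-plane layer — they define the
  mapping from 2D detector coordinates to 3D plane coordinates, and
* *control* markers in a layer between plane and focus — rays through a
  control marker and its imaged plane point all pass through the roentgen
  focus, so the focus is recovered by least-squares ray intersection.

A 3D marker position is then reconstructed as the midpoint of the common
perpendicular between the two back-projected focus-to-image rays; the
length of that perpendicular (the crossing-line distance) is a per-point
quality measure.

The detector is modelled as flat with a projective (homography) mapping
between detector coordinates and the fiducial plane; marker identities
are assumed matched (image processing is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "CalibrationCage",
    "ImageDetections",
    "ProjectionGeometry",
    "ReconstructionResult",
    "QCFinding",
    "calibrate_image",
    "reconstruct_point",
    "validate_acquisition",
    "CalibrationError",
]

MIN_FIDUCIALS = 4
MIN_CONTROLS = 2
#: control-ray residual (mm) above which calibration attaches a warning
FOCUS_RESIDUAL_WARN_MM = 0.5
#: rays closer to parallel than this are refused for triangulation
MIN_RAY_ANGLE_DEG = 1.0


class CalibrationError(ValueError):
    """Raised for unusable calibration input (too few or degenerate markers)."""


@dataclass
class CalibrationCage:
    """Known marker layout of a calibration cage, in the RSA global frame."""

    cage_type: str  # "uniplanar" | "biplanar"
    fiducials: Mapping[str, np.ndarray]
    controls: Mapping[str, np.ndarray]
    beam_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if self.cage_type not in ("uniplanar", "biplanar"):
            raise ValueError(f"unknown cage type {self.cage_type!r}")
        if self.beam_angle_deg is None:
            self.beam_angle_deg = 40.0 if self.cage_type == "uniplanar" else 90.0
        self.fiducials = {k: np.asarray(v, dtype=float) for k, v in self.fiducials.items()}
        self.controls = {k: np.asarray(v, dtype=float) for k, v in self.controls.items()}


@dataclass
class ImageDetections:
    """Labeled 2D detections on one detector, with acquisition metadata."""

    image_id: str
    points: Mapping[str, np.ndarray]
    dpi: float = 150.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        for k, v in self.points.items():
            if v.shape != (2,) or not np.all(np.isfinite(v)):
                raise ValueError(f"detection {k!r}: expected a finite 2-vector")


@dataclass
class ProjectionGeometry:
    """Calibrated projection: plane parameterization, homography and focus."""

    image_id: str
    plane_origin: np.ndarray
    plane_axes: np.ndarray  # (3, 2), orthonormal in-plane axes
    homography: np.ndarray  # (3, 3), detector (u, v, 1) -> plane coords (s, t, w)
    focus: np.ndarray
    #: RMS re-projection residual of the control markers on the plane (mm)
    control_ray_residual_mm: float = 0.0
    fiducial_residual_mm: float = 0.0
    warnings: list[str] = field(default_factory=list)

    def map_to_plane(self, uv: np.ndarray) -> np.ndarray:
        """Map a 2D detector point to its 3D location on the image plane."""
        uv = np.asarray(uv, dtype=float)
        s, t, w = self.homography @ np.array([uv[0], uv[1], 1.0])
        return self.plane_origin + self.plane_axes @ np.array([s / w, t / w])


@dataclass
class ReconstructionResult:
    """Reconstructed 3D marker positions with per-point crossing distances."""

    positions: dict[str, np.ndarray]
    crossing_distance_mm: dict[str, float]
    excluded: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class QCFinding:
    """One acquisition-quality finding: the field, its value and the limit."""

    field: str
    value: object
    limit: object
    message: str


def _fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: (origin, (3,2) orthonormal axes)."""
    origin = points.mean(axis=0)
    _, sv, Vt = np.linalg.svd(points - origin)
    if sv[1] / sv[0] < 1e-9:
        raise CalibrationError("fiducial layout is degenerate (collinear)")
    return origin, Vt[:2].T


def _fit_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """DLT homography mapping 2D src -> 2D dst with Hartley normalization."""

    def normalizer(pts: np.ndarray) -> np.ndarray:
        c = pts.mean(axis=0)
        scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
        T = np.array([[scale, 0, -scale * c[0]], [0, scale, -scale * c[1]], [0, 0, 1]])
        return T

    Ts, Td = normalizer(src), normalizer(dst)
    sh = (np.column_stack([src, np.ones(len(src))]) @ Ts.T)[:, :2]
    dh = (np.column_stack([dst, np.ones(len(dst))]) @ Td.T)[:, :2]
    rows = []
    for (x, y), (u, v) in zip(sh, dh):
        rows.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        rows.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    A = np.asarray(rows)
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] / sv[0] < 1e-12:
        raise CalibrationError("fiducial layout is degenerate for homography fit")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    return H / H[2, 2]


def _nearest_point_to_lines(
    points_on_lines: np.ndarray, directions: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares point minimizing distance to a bundle of 3D lines."""
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for p, d in zip(points_on_lines, directions):
        d = d / np.linalg.norm(d)
        P = np.eye(3) - np.outer(d, d)
        A += P
        b += P @ p
    x = np.linalg.solve(A, b)
    dists = [
        np.linalg.norm((np.eye(3) - np.outer(d / np.linalg.norm(d), d / np.linalg.norm(d))) @ (x - p))
        for p, d in zip(points_on_lines, directions)
    ]
    return x, float(np.sqrt(np.mean(np.square(dists))))


def calibrate_image(cage: CalibrationCage, detections: ImageDetections) -> ProjectionGeometry:
    """Calibrate one projection from the cage markers visible in the image.

    The fiducials detected in this image fix the detector-to-plane
    homography; the control markers then locate the roentgen focus as the
    least-squares intersection of the control rays.
    """
    fid_ids = sorted(set(cage.fiducials) & set(detections.points))
    ctl_ids = sorted(set(cage.controls) & set(detections.points))
    if len(fid_ids) < MIN_FIDUCIALS:
        raise CalibrationError(
            f"insufficient fiducials: need >= {MIN_FIDUCIALS}, matched {len(fid_ids)}"
        )
    if len(ctl_ids) < MIN_CONTROLS:
        raise CalibrationError(
            f"insufficient control markers: need >= {MIN_CONTROLS}, matched {len(ctl_ids)}"
        )
    fid_3d = np.array([cage.fiducials[i] for i in fid_ids])
    origin, axes = _fit_plane(fid_3d)
    plane_st = (fid_3d - origin) @ axes  # in-plane 2D coordinates
    uv = np.array([detections.points[i] for i in fid_ids])
    H = _fit_homography(uv, plane_st)

    geom = ProjectionGeometry(
        image_id=detections.image_id,
        plane_origin=origin,
        plane_axes=axes,
        homography=H,
        focus=np.zeros(3),
    )
    mapped = np.array([geom.map_to_plane(detections.points[i]) for i in fid_ids])
    geom.fiducial_residual_mm = float(
        np.sqrt(np.mean(np.sum((mapped - fid_3d) ** 2, axis=1)))
    )

    ctl_plane = np.array([geom.map_to_plane(detections.points[i]) for i in ctl_ids])
    ctl_3d = np.array([cage.controls[i] for i in ctl_ids])
    directions = ctl_plane - ctl_3d
    focus, _ = _nearest_point_to_lines(ctl_3d, directions)
    geom.focus = focus
    plane_normal = np.cross(axes[:, 0], axes[:, 1])
    # reprojection residual: project each control from the estimated focus
    # onto the plane and compare with its mapped image point (same scale
    # as the detector noise)
    reproj = []
    for c, p in zip(ctl_3d, ctl_plane):
        d = c - focus
        s = ((origin - focus) @ plane_normal) / (d @ plane_normal)
        reproj.append(np.linalg.norm(focus + s * d - p))
    residual = float(np.sqrt(np.mean(np.square(reproj))))
    geom.control_ray_residual_mm = residual
    if abs((focus - origin) @ plane_normal) < 1e-6:
        raise CalibrationError("estimated focus lies on the image plane")
    if residual > FOCUS_RESIDUAL_WARN_MM:
        geom.warnings.append(
            f"control-ray residual {residual:.3f} mm exceeds {FOCUS_RESIDUAL_WARN_MM} mm"
        )
    return geom


def reconstruct_point(
    geom_a: ProjectionGeometry,
    geom_b: ProjectionGeometry,
    uv_a: np.ndarray,
    uv_b: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Triangulate one marker from its two detections.

    Returns the midpoint of the common perpendicular between the two
    back-projected rays and the crossing-line distance (mm).
    """
    pa, da = geom_a.focus, geom_a.map_to_plane(uv_a) - geom_a.focus
    pb, db = geom_b.focus, geom_b.map_to_plane(uv_b) - geom_b.focus
    da = da / np.linalg.norm(da)
    db = db / np.linalg.norm(db)
    cosang = np.clip(abs(da @ db), 0.0, 1.0)
    if np.degrees(np.arccos(cosang)) < MIN_RAY_ANGLE_DEG:
        raise CalibrationError("ill-conditioned reconstruction: rays nearly parallel")
    # closest points: pa + s*da, pb + t*db
    r = pa - pb
    a_dot_b = da @ db
    denom = 1.0 - a_dot_b**2
    s = (a_dot_b * (r @ db) - (r @ da)) / denom
    t = ((r @ db) - a_dot_b * (r @ da)) / denom
    qa = pa + s * da
    qb = pb + t * db
    return (qa + qb) / 2.0, float(np.linalg.norm(qa - qb))


def reconstruct_markers(
    geom_a: ProjectionGeometry,
    geom_b: ProjectionGeometry,
    detections_a: ImageDetections,
    detections_b: ImageDetections,
    marker_ids: list[str] | None = None,
) -> ReconstructionResult:
    """Triangulate all markers visible in both images.

    Markers visible in only one image are excluded with reason
    ``"occluded"``; the exclusion propagates to the flow report.
    """
    ids = marker_ids if marker_ids is not None else sorted(
        set(detections_a.points) | set(detections_b.points)
    )
    positions: dict[str, np.ndarray] = {}
    crossing: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for mid in ids:
        in_a = mid in detections_a.points
        in_b = mid in detections_b.points
        if not (in_a and in_b):
            excluded[mid] = "occluded" if (in_a or in_b) else "not detected"
            continue
        pos, dist = reconstruct_point(
            geom_a, geom_b, detections_a.points[mid], detections_b.points[mid]
        )
        positions[mid] = pos
        crossing[mid] = dist
    return ReconstructionResult(positions=positions, crossing_distance_mm=crossing, excluded=excluded)


def validate_acquisition(
    meta: Mapping[str, object],
    modality: str = "RSA",
    thresholds: "object | None" = None,
) -> list[QCFinding]:
    """Check acquisition metadata against the guideline minima.

    For plain radiographic RSA: detector resolution >= 150 DPI and
    grayscale depth >= 8 bits. For CT-RSA: slice thickness <= 1.0 mm and
    pixel size <= 0.5 mm, and the metal-artifact-reduction flag and
    effective dose must be recorded. Validation reports findings but
    never aborts.
    """
    from .quality import QCThresholds  # local import to avoid a cycle

    thr = thresholds if thresholds is not None else QCThresholds()
    findings: list[QCFinding] = []
    if modality == "RSA":
        dpi = meta.get("dpi")
        if dpi is None:
            findings.append(QCFinding("dpi", None, thr.dpi_min, "DPI not recorded"))
        elif dpi < thr.dpi_min:
            findings.append(
                QCFinding("dpi", dpi, thr.dpi_min, f"DPI {dpi} below minimum {thr.dpi_min}")
            )
        depth = meta.get("bit_depth")
        if depth is None:
            findings.append(QCFinding("bit_depth", None, thr.bit_depth_min, "bit depth not recorded"))
        elif depth < thr.bit_depth_min:
            findings.append(
                QCFinding(
                    "bit_depth", depth, thr.bit_depth_min,
                    f"grayscale depth {depth} bits below minimum {thr.bit_depth_min}",
                )
            )
    elif modality == "CT_RSA":
        slice_mm = meta.get("slice_thickness_mm")
        if slice_mm is None:
            findings.append(
                QCFinding("slice_thickness_mm", None, thr.ct_slice_max_mm, "slice thickness not recorded")
            )
        elif slice_mm > thr.ct_slice_max_mm:
            findings.append(
                QCFinding(
                    "slice_thickness_mm", slice_mm, thr.ct_slice_max_mm,
                    f"slice thickness {slice_mm} mm above recommended maximum {thr.ct_slice_max_mm} mm",
                )
            )
        pixel_mm = meta.get("pixel_size_mm")
        if pixel_mm is None:
            findings.append(
                QCFinding("pixel_size_mm", None, thr.ct_pixel_max_mm, "pixel size not recorded")
            )
        elif pixel_mm > thr.ct_pixel_max_mm:
            findings.append(
                QCFinding(
                    "pixel_size_mm", pixel_mm, thr.ct_pixel_max_mm,
                    f"pixel size {pixel_mm} mm above recommended maximum {thr.ct_pixel_max_mm} mm",
                )
            )
        if meta.get("metal_artifact_reduction") is None:
            findings.append(
                QCFinding(
                    "metal_artifact_reduction", None, "required",
                    "metal-artifact-reduction use not recorded",
                )
            )
        if meta.get("effective_dose_msv") is None:
            findings.append(
                QCFinding("effective_dose_msv", None, "required", "effective radiation dose not recorded")
            )
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return findings
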