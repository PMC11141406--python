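"""Shared fixtures and independent oracles for the rsakit test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from rsakit.geometry import FitQuality
from rsakit.migration import CoordinateSystemSpec, MigrationResult


def brute_force_rigid_fit(reference: np.ndarray, moving: np.ndarray):
    """Independent oracle: nonlinear least squares over axis-angle + translation.

    Minimizes the same objective as the SVD superposition but through a
    generic optimizer with several restarts, sharing no code with the
    implementation under test.
    """
    ref = np.asarray(reference, float)
    mov = np.asarray(moving, float)

    def residuals(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        return (mov @ R.T + params[3:] - ref).ravel()

    best = None
    for rotvec0 in (np.zeros(3), np.array([0.1, -0.2, 0.3]), np.array([-1.0, 0.5, 0.8])):
        x0 = np.concatenate([rotvec0, ref.mean(axis=0) - mov.mean(axis=0)])
        sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    R = Rotation.from_rotvec(best.x[:3]).as_matrix()
    t = best.x[3:]
    me = float(np.sqrt(np.mean(np.sum((mov @ R.T + t - ref) ** 2, axis=1))))
    return R, t, me


@pytest.fixture
def rng():
    return np.random.default_rng(20240530)


def make_result(
    patient_id="p1",
    followup_exam_id="p1-fu1",
    days=365,
    tx=0.0, ty=0.0, tz=0.0, rx=0.0, ry=0.0, rz=0.0,
    me_ref=0.1, cn_ref=50.0, n_ref=6,
    me_mov=0.1, cn_mov=30.0, n_mov=4,
    side="right",
    marker_method="all",
    point_motions=None,
) -> MigrationResult:
    """Minimal MigrationResult for statistics/gating tests."""
    t = np.array([tx, ty, tz])
    r = np.array([rx, ry, rz])
    pm = point_motions if point_motions is not None else {"p0": t.copy()}
    mtpm_pt = max(sorted(pm), key=lambda k: np.linalg.norm(pm[k]), default="")
    return MigrationResult(
        patient_id=patient_id,
        baseline_exam_id=f"{patient_id}-base",
        followup_exam_id=followup_exam_id,
        body_id="prosthesis",
        days_since_surgery=days,
        tx=tx, ty=ty, tz=tz, rx=rx, ry=ry, rz=rz,
        tt=float(np.linalg.norm(t)),
        tr=float(np.linalg.norm(r)),
        mtpm=float(max((np.linalg.norm(v) for v in pm.values()), default=0.0)),
        mtpm_point=str(mtpm_pt),
        point_motions=pm,
        quality_reference=FitQuality(me_ref, cn_ref, n_ref),
        quality_migrating=FitQuality(me_mov, cn_mov, n_mov),
        marker_method=marker_method,
        cs=CoordinateSystemSpec(),
        side=side,
    )
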