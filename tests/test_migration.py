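"""Migration computation, MTPM, interval migration and conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rsakit.geometry import (
    InsufficientMarkersError,
    MarkerObservation,
    RigidBodyObservation,
    RigidTransform,
    rotation_from_euler,
)
from rsakit.migration import (
    CoordinateSystemSpec,
    Examination,
    compute_migration,
    convert_frame,
    interval_migration,
    mtpm,
    point_motion,
    select_markers,
    to_right_side,
)

from conftest import make_result


def make_exam(exam_id, bone_pts, pros_pts, patient="p1", side="right", days=0,
              kind="followup", bone_ids=None, pros_ids=None):
    bone_ids = bone_ids or [f"b{i}" for i in range(len(bone_pts))]
    pros_ids = pros_ids or [f"p{i}" for i in range(len(pros_pts))]
    return Examination(
        exam_id=exam_id, patient_id=patient, side=side, days_since_surgery=days,
        kind=kind,
        bodies={
            "bone": RigidBodyObservation(
                "bone", [MarkerObservation(i, p, role="bone") for i, p in zip(bone_ids, bone_pts)]
            ),
            "prosthesis": RigidBodyObservation(
                "prosthesis",
                [MarkerObservation(i, p, role="prosthesis") for i, p in zip(pros_ids, pros_pts)]
            ),
        },
    )


@pytest.fixture
def configs(rng):
    bone = rng.uniform(-40, 40, (6, 3))
    pros = rng.uniform(-20, 20, (4, 3)) + np.array([0, 0, 40.0])
    return bone, pros


def random_rigid(rng):
    from scipy.spatial.transform import Rotation

    return RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.uniform(-30, 30, 3))


class TestComputeMigration:
    def test_zero_motion(self, configs):
        bone, pros = configs
        base = make_exam("base", bone, pros, kind="baseline")
        fu = make_exam("fu", bone, pros)
        res = compute_migration(base, fu)
        for v in res.components().values():
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_invariant_to_repositioning(self, configs, rng):
        bone, pros = configs
        shift = np.array([0.5, 0.0, 0.0])
        repos = random_rigid(rng)
        base = make_exam("base", bone, pros, kind="baseline")
        fu = make_exam("fu", repos.apply(bone), repos.apply(pros + shift))
        res = compute_migration(base, fu)
        assert res.tx == pytest.approx(0.5, abs=1e-9)
        assert (res.ty, res.tz) == pytest.approx((0.0, 0.0), abs=1e-9)
        assert (res.rx, res.ry, res.rz) == pytest.approx((0, 0, 0), abs=1e-9)
        assert res.tt == pytest.approx(0.5, abs=1e-9)
        assert res.mtpm == pytest.approx(0.5, abs=1e-9)  # translation: mtpm == tt

    def test_rotation_about_migration_axis_through_origin(self, configs):
        bone, pros = configs
        origin = pros.mean(axis=0)
        R = rotation_from_euler([0.0, 2.0, 0.0])
        moved = (pros - origin) @ R.T + origin
        base = make_exam("base", bone, pros, kind="baseline")
        fu = make_exam("fu", bone, moved)
        res = compute_migration(base, fu)
        assert res.ry == pytest.approx(2.0, abs=1e-9)
        assert (res.rx, res.rz) == pytest.approx((0.0, 0.0), abs=1e-9)
        assert (res.tx, res.ty, res.tz) == pytest.approx((0, 0, 0), abs=1e-9)
        # point motion grows with distance from the rotation axis; MTPM is
        # attained at the evaluated point farthest from the axis
        dists = {
            f"p{i}": np.hypot(p[0] - origin[0], p[2] - origin[2])
            for i, p in enumerate(pros)
        }
        motions = {pid: np.linalg.norm(v) for pid, v in res.point_motions.items()}
        assert max(motions, key=motions.get) == max(dists, key=dists.get)
        # brute-force check of the MTPM value
        expected = max(
            np.linalg.norm(((p - origin) @ R.T + origin) - p) for p in pros
        )
        assert res.mtpm == pytest.approx(expected, abs=1e-12)

    def test_missing_body_is_reported(self, configs):
        bone, pros = configs
        base = make_exam("base", bone, pros, kind="baseline")
        fu = make_exam("fu", bone, pros)
        del fu.bodies["prosthesis"]
        with pytest.raises(ValueError, match="prosthesis"):
            compute_migration(base, fu)

    def test_insufficient_shared_markers_names_body(self, configs):
        bone, pros = configs
        base = make_exam("base", bone, pros, kind="baseline")
        fu = make_exam("fu", bone, pros[:2], pros_ids=["p0", "p1"])
        with pytest.raises(InsufficientMarkersError, match="prosthesis"):
            compute_migration(base, fu)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_repositioning_invariance_property(self, seed):
        rng = np.random.default_rng(seed)
        bone = rng.uniform(-40, 40, (5, 3))
        pros = rng.uniform(-20, 20, (4, 3))
        mig = random_rigid(rng)
        base = make_exam("base", bone, pros, kind="baseline")
        fu_plain = make_exam("fu", bone, mig.apply(pros))
        repos = random_rigid(rng)
        fu_moved = make_exam("fu", repos.apply(bone), repos.apply(mig.apply(pros)))
        r1 = compute_migration(base, fu_plain)
        r2 = compute_migration(base, fu_moved)
        for k, v in r1.components().items():
            assert r2.components()[k] == pytest.approx(v, abs=1e-8)

    def test_mtpm_invariant_under_frame_orientation_but_components_not(self, configs, rng):
        bone, pros = configs
        mig = random_rigid(rng)
        # keep the motion small enough to be a plausible migration
        small = RigidTransform(rotation_from_euler([1.0, -0.5, 0.7]), np.array([0.3, -0.2, 0.4]))
        base = make_exam("base", bone, pros, kind="baseline")
        fu = make_exam("fu", bone, small.apply(pros))
        from scipy.spatial.transform import Rotation

        A = Rotation.random(rng=np.random.default_rng(5)).as_matrix()
        r_default = compute_migration(base, fu)
        r_rotated = compute_migration(base, fu, cs=CoordinateSystemSpec(axes=A))
        assert r_rotated.mtpm == pytest.approx(r_default.mtpm, abs=1e-9)
        assert r_rotated.tt == pytest.approx(r_default.tt, abs=1e-9)
        assert abs(r_rotated.tx - r_default.tx) > 1e-6  # signed components move

    def test_tt_tr_equal_component_norms(self, configs):
        bone, pros = configs
        small = RigidTransform(rotation_from_euler([1.0, 2.0, -1.5]), np.array([0.3, -0.2, 0.4]))
        base = make_exam("base", bone, pros, kind="baseline")
        fu = make_exam("fu", bone, small.apply(pros))
        res = compute_migration(base, fu)
        assert res.tt == pytest.approx(np.linalg.norm(res.translations), abs=1e-12)
        assert res.tr == pytest.approx(np.linalg.norm(res.rotations), abs=1e-12)


class TestSelectMarkers:
    def _series(self, configs):
        bone, pros = configs
        base = make_exam("base", bone, pros, kind="baseline", days=0)
        fu12 = make_exam("fu12", bone, pros, days=365)
        fu24 = make_exam("fu24", bone, pros, days=730)
        return base, fu12, fu24

    def test_no_occlusion_methods_identical(self, configs):
        base, fu12, fu24 = self._series(configs)
        cons = select_markers(base, [fu12, fu24], "consistent")
        alls = select_markers(base, [fu12, fu24], "all")
        assert cons["prosthesis"]["fu12"] == alls["prosthesis"]["fu12"]
        assert cons["bone"]["fu24"] == alls["bone"]["fu24"]

    def test_late_occlusion_changes_early_timepoints_only_for_consistent(self, configs):
        bone, pros = configs
        base = make_exam("base", bone, pros, kind="baseline")
        fu12 = make_exam("fu12", bone, pros, days=365)
        fu24 = make_exam("fu24", bone[:5], pros, days=730,
                         bone_ids=[f"b{i}" for i in range(5)])  # b5 occluded at 24 m
        cons = select_markers(base, [fu12, fu24], "consistent")
        assert "b5" not in cons["bone"]["fu12"]  # excluded everywhere
        alls = select_markers(base, [fu12, fu24], "all")
        assert "b5" in alls["bone"]["fu12"]      # retained while visible
        assert "b5" not in alls["bone"]["fu24"]

    def test_consistent_intersection_below_three_errors(self, configs):
        bone, pros = configs
        base = make_exam("base", bone, pros, kind="baseline")
        fu = make_exam("fu", bone[:2], pros, bone_ids=["b0", "b1"])
        with pytest.raises(InsufficientMarkersError, match="all-marker"):
            select_markers(base, [fu], "consistent")


class TestMtpmAndPointMotion:
    def test_pure_translation_equals_norm_for_any_point_set(self, rng):
        t = np.array([0.3, -0.4, 1.2])
        T = RigidTransform(np.eye(3), t)
        pts = {f"q{i}": p for i, p in enumerate(rng.uniform(-50, 50, (6, 3)))}
        val, _ = mtpm(pts, T)
        assert val == pytest.approx(np.linalg.norm(t), abs=1e-12)

    def test_rotation_argmax_at_farther_point(self):
        T = RigidTransform(rotation_from_euler([1.0, 0.0, 0.0]), np.zeros(3))
        pts = {"near": np.array([0.0, 0.0, 10.0]), "far": np.array([0.0, 0.0, 50.0])}
        val, argmax = mtpm(pts, T)
        assert argmax == "far"
        brute = max(np.linalg.norm(T.apply(p) - p) for p in pts.values())
        assert val == pytest.approx(brute, abs=1e-12)
        # 1° rotation at 50 mm: 2·50·sin(0.5°)
        assert val == pytest.approx(2 * 50 * np.sin(np.radians(0.5)), abs=1e-9)

    def test_mtpm_scales_with_point_set_size(self):
        T = RigidTransform(rotation_from_euler([1.0, 0.0, 0.0]), np.zeros(3))
        pts = {"a": np.array([0.0, 5.0, 10.0]), "b": np.array([0.0, -3.0, 50.0])}
        v1, _ = mtpm(pts, T)
        v2, _ = mtpm({k: 2 * v for k, v in pts.items()}, T)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_empty_point_set_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mtpm({}, RigidTransform.identity())

    def test_point_motion_identity_and_translation(self):
        p = np.array([1.0, 2.0, 3.0])
        v, n = point_motion(p, RigidTransform.identity())
        assert n == 0.0
        t = np.array([0.1, 0.2, -0.3])
        v, n = point_motion(p, RigidTransform(np.eye(3), t))
        np.testing.assert_allclose(v, t)
        assert n == pytest.approx(np.linalg.norm(t))


class TestIntervalMigration:
    def test_identical_results_give_zero(self):
        m = make_result(tx=1.0, ry=2.0, days=365)
        d = interval_migration(m, m)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in d.components().values())

    def test_component_subtraction(self):
        m1 = make_result(tx=0.4, followup_exam_id="fu12", days=365)
        m2 = make_result(tx=1.0, followup_exam_id="fu24", days=730)
        d = interval_migration(m1, m2)
        assert d.tx == pytest.approx(0.6)
        assert d.tt == pytest.approx(0.6)

    def test_large_rotation_flagged(self):
        m1 = make_result(rx=10.0, followup_exam_id="fu12")
        m2 = make_result(ry=10.0, followup_exam_id="fu24")
        d = interval_migration(m1, m2)
        assert any("approximate" in w for w in d.warnings)

    def test_provenance_mismatch_rejected(self):
        m1 = make_result(marker_method="all")
        m2 = make_result(marker_method="consistent")
        with pytest.raises(ValueError, match="provenance"):
            interval_migration(m1, m2)

    def test_mtpm_recomputed_from_differenced_point_motions(self):
        pm1 = {"a": np.array([0.1, 0.0, 0.0]), "b": np.array([0.0, 0.5, 0.0])}
        pm2 = {"a": np.array([0.4, 0.0, 0.0]), "b": np.array([0.0, 0.6, 0.0])}
        m1 = make_result(point_motions=pm1, followup_exam_id="fu12")
        m2 = make_result(point_motions=pm2, followup_exam_id="fu24")
        d = interval_migration(m1, m2)
        assert d.mtpm == pytest.approx(0.3)
        assert d.mtpm_point == "a"


class TestSideConversion:
    def test_left_rule(self):
        m = make_result(tx=1, ty=2, tz=3, rx=4, ry=5, rz=6, side="left")
        c = to_right_side(m)
        assert (c.tx, c.ty, c.tz, c.rx, c.ry, c.rz) == (-1, 2, 3, 4, -5, -6)
        assert c.side_convention == "converted_to_right"
        assert (c.tt, c.tr, c.mtpm) == (m.tt, m.tr, m.mtpm)  # norms unchanged

    def test_right_passthrough(self):
        m = make_result(tx=1.0, side="right")
        assert to_right_side(m) is m

    def test_involution(self):
        m = make_result(tx=1, ry=5, rz=6, side="left")
        twice = to_right_side(to_right_side(m), side="left")
        assert (twice.tx, twice.ry, twice.rz) == (m.tx, m.ry, m.rz)

    def test_unknown_side_rejected(self):
        m = make_result()
        with pytest.raises(ValueError, match="side"):
            to_right_side(m, side="bilateral")


class TestFrameConversion:
    def test_superior_axis(self):
        np.testing.assert_allclose(
            convert_frame(np.array([0.0, 1.0, 0.0]), "RSA_GLOBAL", "DICOM_LPS"),
            [0.0, 0.0, 1.0], atol=1e-15,
        )

    def test_anterior_axis(self):
        np.testing.assert_allclose(
            convert_frame(np.array([0.0, 0.0, 1.0]), "RSA_GLOBAL", "DICOM_LPS"),
            [0.0, -1.0, 0.0], atol=1e-15,
        )

    def test_round_trip_and_proper_rotation(self, rng):
        v = rng.normal(size=3)
        there = convert_frame(v, "RSA_GLOBAL", "DICOM_LPS")
        back = convert_frame(there, "DICOM_LPS", "RSA_GLOBAL")
        np.testing.assert_allclose(back, v, atol=1e-15)
        from rsakit.migration import RSA_TO_LPS

        assert np.linalg.det(RSA_TO_LPS) == pytest.approx(1.0)

    def test_transform_conversion_round_trip(self, rng):
        T = random_rigid(rng)
        back = convert_frame(convert_frame(T, "RSA_GLOBAL", "DICOM_LPS"), "DICOM_LPS", "RSA_GLOBAL")
        np.testing.assert_allclose(back.rotation, T.rotation, atol=1e-12)
        np.testing.assert_allclose(back.translation, T.translation, atol=1e-12)

    def test_unknown_frame_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            convert_frame(np.zeros(3), "RSA_GLOBAL", "SCANNER")
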