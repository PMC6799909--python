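"""Rigid fitting (Kabsch), scan registration and virtual-marker imputation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from markermorph import (
    DegenerateGeometryError,
    InsufficientMarkersError,
    LandmarkSet,
    RigidTransform,
    VirtualMarkerModel,
    fit_rigid,
    impute_virtual_markers,
    register_scan,
)

from conftest import random_rotation

TETRA = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


class TestRigidTransform:
    def test_reflection_rejected_on_construction(self):
        with pytest.raises(DegenerateGeometryError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_invert_identity(self):
        ident = RigidTransform.identity()
        assert np.allclose(ident.inverse().matrix, np.eye(4))

    def test_apply_translation_to_origin(self):
        t = RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0]))
        assert np.allclose(t.apply(np.zeros(3)), (1, 2, 3))

    def test_group_axioms_on_random_transforms(self):
        rng = np.random.default_rng(23)
        pts = rng.normal(scale=30, size=(100, 3))
        for _ in range(10):
            a = RigidTransform(random_rotation(rng), rng.normal(scale=20, size=3))
            b = RigidTransform(random_rotation(rng), rng.normal(scale=20, size=3))
            # T^-1 o T == identity on points
            assert np.abs(a.inverse().apply(a.apply(pts)) - pts).max() < 1e-9
            # (A o B)(p) == A(B(p))
            assert np.abs(a.compose(b).apply(pts) - a.apply(b.apply(pts))).max() < 1e-9
        assert np.allclose(
            RigidTransform.from_matrix(a.matrix).matrix, a.matrix)


class TestFitRigid:
    def test_identical_point_sets_give_identity(self):
        fit = fit_rigid(TETRA, TETRA)
        assert np.abs(fit.transform.rotation - np.eye(3)).max() <= 1e-9
        assert np.abs(fit.transform.translation).max() <= 1e-9
        assert fit.rms_mm <= 1e-12

    def test_recovers_quarter_turn_and_translation(self):
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        target = TETRA @ rot.T + np.array([5.0, 0, 0])
        fit = fit_rigid(TETRA, target)
        assert np.abs(fit.transform.rotation - rot).max() <= 1e-9
        assert np.abs(fit.transform.translation - (5, 0, 0)).max() <= 1e-9
        assert fit.rms_mm <= 1e-9

    def test_collinear_source_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            fit_rigid(line, line)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientMarkersError):
            fit_rigid(TETRA[:2], TETRA[:2])

    def test_reflected_target_still_yields_proper_rotation(self):
        """When the best orthogonal map is a reflection, the returned
        rotation must still be proper (det +1)."""
        target = TETRA @ np.diag([1.0, 1.0, -1.0])
        fit = fit_rigid(TETRA, target)
        assert np.isclose(np.linalg.det(fit.transform.rotation), 1.0, atol=1e-9)
        assert fit.rms_mm > 0  # a reflection cannot be matched exactly

    def test_recovers_1000_random_proper_transforms(self):
        rng = np.random.default_rng(29)
        worst_r = worst_t = 0.0
        for _ in range(1000):
            rot = random_rotation(rng)
            trans = rng.normal(scale=50, size=3)
            fit = fit_rigid(TETRA, TETRA @ rot.T + trans)
            worst_r = max(worst_r, float(np.abs(fit.transform.rotation - rot).max()))
            worst_t = max(worst_t, float(np.abs(fit.transform.translation - trans).max()))
        assert worst_r <= 1e-9 and worst_t <= 1e-9

    def test_agrees_with_scipy_align_vectors_on_noisy_data(self):
        """Independent cross-check: scipy's Kabsch solver finds the same
        rotation on noisy (non-exact) correspondences."""
        rng = np.random.default_rng(31)
        src = rng.normal(scale=20, size=(8, 3))
        rot = random_rotation(rng)
        tgt = src @ rot.T + rng.normal(scale=0.5, size=src.shape)
        fit = fit_rigid(src, tgt)
        ours = fit.transform.rotation
        ref, _ = Rotation.align_vectors(tgt - tgt.mean(0), src - src.mean(0))
        assert np.abs(ours - ref.as_matrix()).max() <= 1e-8

    def test_matches_angle_grid_search_oracle(self):
        """Exhaustive single-axis angle search agrees with the
        closed-form solution within the grid resolution."""
        rng = np.random.default_rng(37)
        axis = np.array([0.0, 0.0, 1.0])
        true_angle = 37.0
        rot = Rotation.from_rotvec(np.deg2rad(true_angle) * axis).as_matrix()
        target = TETRA @ rot.T
        fit = fit_rigid(TETRA, target)

        def cost(angle_deg):
            r = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
            src_c = TETRA - TETRA.mean(0)
            tgt_c = target - target.mean(0)
            return float(((src_c @ r.T - tgt_c) ** 2).sum())

        grid = np.arange(0.0, 360.0, 0.05)
        best = grid[int(np.argmin([cost(a) for a in grid]))]
        got = np.rad2deg(
            np.arccos(np.clip((np.trace(fit.transform.rotation) - 1) / 2, -1, 1)))
        assert abs(got - best) <= 0.05
        assert abs(got - true_angle) <= 1e-9


def _scap_landmarks(points):
    return LandmarkSet(scapula=points,
                       humerus={"HH": (0.0, 0, 0), "ME": (-15.0, 0, -300),
                                "LE": (15.0, 0, -300)})


REF_SCAP = {"AA": np.array([10.0, 0, 0]), "TS": np.array([-30.0, 5, 0]),
            "AI": np.array([-25.0, -80, -10])}


class TestRegisterScan:
    def test_identical_landmarks_give_identity(self):
        lm = _scap_landmarks(dict(REF_SCAP))
        fit = register_scan(lm, lm)
        assert np.abs(fit.transform.matrix - np.eye(4)).max() <= 1e-9

    def test_recovers_known_motion(self):
        rng = np.random.default_rng(41)
        rot, trans = random_rotation(rng), np.array([3.0, -7.0, 12.0])
        moved = {k: rot @ v + trans for k, v in REF_SCAP.items()}
        fit = register_scan(_scap_landmarks(dict(REF_SCAP)), _scap_landmarks(moved))
        # the registration is the inverse motion
        assert np.abs(fit.transform.rotation - rot.T).max() <= 1e-9
        for k, v in REF_SCAP.items():
            assert np.abs(fit.transform.apply(moved[k]) - v).max() <= 1e-9

    def test_rms_bounded_under_landmark_noise(self):
        """0.5 mm iid landmark perturbation: registration RMS <= 0.9 mm
        across 100 seeded trials."""
        rng = np.random.default_rng(43)
        ref = _scap_landmarks(dict(REF_SCAP))
        worst = 0.0
        for _ in range(100):
            noisy = {k: v + rng.normal(scale=0.5, size=3)
                     for k, v in REF_SCAP.items()}
            fit = register_scan(ref, _scap_landmarks(noisy))
            worst = max(worst, fit.rms_mm)
        assert worst <= 0.9

    def test_landmark_name_mismatch_rejected(self):
        other = {"AA": REF_SCAP["AA"], "TS": REF_SCAP["TS"],
                 "XX": REF_SCAP["AI"]}
        with pytest.raises(Exception, match="XX"):
            register_scan(_scap_landmarks(dict(REF_SCAP)), _scap_landmarks(other))


H_REF = {"H1": np.array([6.0, 6, -4]), "H2": np.array([7.0, 16, -3]),
         "H3": np.array([5.0, 26, -6])}
V_REF = {"V1": np.array([0.0, 6, 1]), "V2": np.array([0.0, 13, 0.3]),
         "V3": np.array([0.0, 20, -0.4]), "V4": np.array([0.0, 27, -1.1])}


class TestImputeVirtualMarkers:
    def test_unmoved_bone_markers_leave_virtual_markers_unchanged(self):
        model = VirtualMarkerModel(dict(V_REF), dict(H_REF))
        imputed, rms = impute_virtual_markers(model, dict(H_REF))
        assert rms <= 1e-12
        for k, v in V_REF.items():
            assert np.abs(imputed[k] - v).max() <= 1e-9

    def test_rotated_bone_markers_rotate_virtual_markers(self):
        axis = np.array([0.0, 0, 1])
        rot = Rotation.from_rotvec(np.deg2rad(30) * axis).as_matrix()
        model = VirtualMarkerModel(dict(V_REF), dict(H_REF))
        moved = {k: rot @ v for k, v in H_REF.items()}
        imputed, rms = impute_virtual_markers(model, moved)
        assert rms <= 1e-9
        for k, v in V_REF.items():
            assert np.abs(imputed[k] - rot @ v).max() <= 1e-9

    def test_collinear_followup_rejected(self):
        bad = {"H1": np.array([0.0, 0, 0]), "H2": np.array([5.0, 0, 0]),
               "H3": np.array([10.0, 0, 0])}
        model = VirtualMarkerModel(dict(V_REF), dict(H_REF))
        with pytest.raises(DegenerateGeometryError):
            impute_virtual_markers(model, bad)

    def test_missing_bone_marker_rejected(self):
        model = VirtualMarkerModel(dict(V_REF), dict(H_REF))
        with pytest.raises(InsufficientMarkersError, match="H3"):
            impute_virtual_markers(model, {"H1": H_REF["H1"], "H2": H_REF["H2"]})

    def test_measurements_invariant_under_whole_scan_rigid_motion(self):
        """Lengths/areas built from imputed V and co-moved T markers are
        invariant when an entire follow-up scan moves rigidly."""
        from markermorph import length, quad_area
        rng = np.random.default_rng(47)
        t_marks = {"T1": np.array([-12.5, 6.5, 2.0]), "T3": np.array([-13.5, 13.8, 1.0])}
        model = VirtualMarkerModel(dict(V_REF), dict(H_REF))
        base_v, _ = impute_virtual_markers(model, dict(H_REF))
        base_len = length(base_v["V1"], t_marks["T1"])
        base_area = quad_area(base_v["V1"], base_v["V2"], t_marks["T3"], t_marks["T1"])
        for _ in range(10):
            g = RigidTransform(random_rotation(rng), rng.normal(scale=30, size=3))
            moved_h = {k: g.apply(v) for k, v in H_REF.items()}
            moved_t = {k: g.apply(v) for k, v in t_marks.items()}
            v_new, _ = impute_virtual_markers(model, moved_h)
            assert abs(length(v_new["V1"], moved_t["T1"]) - base_len) <= 1e-6
            assert abs(quad_area(v_new["V1"], v_new["V2"], moved_t["T3"],
                                 moved_t["T1"]) - base_area) <= 1e-6
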