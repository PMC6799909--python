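"""Lengths, swap-averaged areas, projected angles, precision and
longitudinal statistics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from markermorph import (
    AnatomicalFrame,
    IllConditionedProjectionError,
    MarkerMorphError,
    MeasurementDefinitions,
    MeasurementRecord,
    StudyValidationError,
    humeral_orientation,
    length,
    longitudinal_summary,
    measure_scan,
    precision_summary,
    projected_angle,
    quad_area,
)

from conftest import random_rotation


class TestLength:
    def test_coincident_points(self):
        assert length((1, 2, 3), (1, 2, 3)) == 0.0

    def test_three_four_five(self):
        assert length((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0, abs=1e-12)

    def test_matches_coordinate_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p, q = rng.normal(scale=40, size=(2, 3))
            expect = np.sqrt(((p - q) ** 2).sum())
            assert abs(length(p, q) - expect) <= 1e-12


def shoelace_planar(pts2d):
    """Shoelace oracle for a simple planar polygon (2-D coords)."""
    x, y = np.asarray(pts2d).T
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestQuadArea:
    def test_planar_unit_square(self):
        assert quad_area((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(1.0)

    def test_collinear_points_give_zero(self):
        pts = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)]
        assert quad_area(*pts) == 0.0

    def test_nonplanar_swap_average_worked_example(self):
        """Both triangulations evaluated by hand: diagonal p1p3 gives
        sqrt(2), diagonal p2p4 gives (sqrt(3)+1)/2; the average is
        ~1.3901."""
        got = quad_area((0, 0, 0), (1, 0, 0), (1, 1, 1), (0, 1, 0))
        expect = (np.sqrt(2) + (np.sqrt(3) + 1) / 2) / 2
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(1.3901, abs=1e-4)

    def test_planar_quads_match_shoelace_oracle(self):
        """1000 random convex planar quads embedded in random 3-D
        orientations agree with the in-plane shoelace formula."""
        rng = np.random.default_rng(5)
        for _ in range(1000):
            # convex planar quad: sorted angles on an ellipse
            ang = np.sort(rng.uniform(0, 2 * np.pi, 4))
            radii = rng.uniform(1, 10, 2)
            pts2 = np.stack([radii[0] * np.cos(ang), radii[1] * np.sin(ang)], axis=1)
            expect = shoelace_planar(pts2)
            rot = random_rotation(rng)
            shift = rng.normal(scale=20, size=3)
            pts3 = np.column_stack([pts2, np.zeros(4)]) @ rot.T + shift
            assert abs(quad_area(*pts3) - expect) <= 1e-9 * max(expect, 1.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(scale=10, size=(4, 3))
        base = quad_area(*pts)
        for _ in range(20):
            rot = random_rotation(rng)
            shift = rng.normal(scale=30, size=3)
            moved = pts @ rot.T + shift
            assert abs(quad_area(*moved) - base) <= 1e-9 * base

    def test_cyclic_relabeling_invariance(self):
        """Rotating the perimeter start point swaps the two
        triangulations; the swap-average is unchanged."""
        rng = np.random.default_rng(9)
        p = rng.normal(scale=10, size=(4, 3))
        base = quad_area(*p)
        assert quad_area(p[1], p[2], p[3], p[0]) == pytest.approx(base, rel=1e-12)
        assert quad_area(p[2], p[3], p[0], p[1]) == pytest.approx(base, rel=1e-12)


class TestProjectedAngle:
    def test_equal_in_plane_vectors(self):
        assert projected_angle((0, 1, 0), (0, 1, 0), (1, 0, 0)) == pytest.approx(0.0)

    def test_forty_five_degrees(self):
        assert projected_angle((0, 0, 1), (0, 1, 1), (1, 0, 0)) == pytest.approx(45.0)

    def test_ninety_degrees(self):
        assert projected_angle((0, 0, 1), (0, 1, 0), (1, 0, 0)) == pytest.approx(90.0)

    def test_projection_removes_normal_component(self):
        # (1,1,0) vs (−1,1,0) onto plane normal x: both project to +/-y? no:
        # projections are (0,1,0) and (0,1,0) -> 0 degrees
        assert projected_angle((1, 1, 0), (-1, 1, 0), (1, 0, 0)) == pytest.approx(0.0)

    def test_vector_parallel_to_normal_is_ill_conditioned(self):
        with pytest.raises(IllConditionedProjectionError):
            projected_angle((1, 0, 0), (0, 1, 0), (1, 0, 0))

    def test_signed_variant_is_antisymmetric(self):
        a = projected_angle((0, 0, 1), (0, 1, 1), (1, 0, 0), signed=True)
        b = projected_angle((0, 1, 1), (0, 0, 1), (1, 0, 0), signed=True)
        assert a == pytest.approx(-b)
        assert abs(a) == pytest.approx(45.0)


def _frame(origin=(0, 0, 0), rot=np.eye(3)):
    rot = np.asarray(rot, float)
    return AnatomicalFrame(np.asarray(origin, float),
                           rot @ (1, 0, 0), rot @ (0, 1, 0), rot @ (0, 0, 1))


class TestHumeralOrientation:
    def test_identical_frames_give_zero_angles(self):
        scap = _frame()
        angles = humeral_orientation(scap, _frame())
        assert all(abs(v) <= 1e-9 for v in angles.values())

    @pytest.mark.parametrize("axis,angle_name", [
        ("axis_anterior", "abduction"),
        ("axis_superior", "external_rotation"),
        ("axis_lateral", "extension"),
    ])
    def test_single_axis_rotations_recovered_exactly(self, axis, angle_name):
        scap = _frame()
        for deg in (5.0, 20.0, 30.0, 85.0):
            rot = Rotation.from_rotvec(np.deg2rad(deg) * getattr(scap, axis)).as_matrix()
            hum = _frame(rot=rot)
            angles = humeral_orientation(scap, hum)
            assert angles[angle_name] == pytest.approx(deg, abs=1e-9)
            others = [v for k, v in angles.items() if k != angle_name]
            assert all(abs(v) <= 1e-9 for v in others)


DEFS = MeasurementDefinitions(
    lengths=(("V1", "T1"), ("T1", "T2")),
    areas=(("V1", "T1", "T2", "V2"),),
)
POS = {
    "V1": np.array([0.0, 0, 0]), "V2": np.array([0.0, 5, 0]),
    "T1": np.array([-10.0, 0, 0]), "T2": np.array([-10.0, 5, 0]),
}


class TestMeasureScan:
    def test_cadaver_layout_has_14_6_3_measures(self, cadaver_spec):
        positions = {m.label: m.center_mm for m in cadaver_spec.markers}
        from markermorph import humeral_frame, scapular_frame
        rec = measure_scan(
            positions, cadaver_spec.measurements,
            scapula=scapular_frame(cadaver_spec.landmarks),
            humerus=humeral_frame(cadaver_spec.landmarks),
        )
        assert len(rec.lengths) == 14
        assert len(rec.areas) == 6
        assert len(rec.angles) == 3
        assert not rec.missing

    def test_missing_marker_flagged_without_aborting_rest(self):
        pos = {k: v for k, v in POS.items() if k != "T2"}
        rec = measure_scan(pos, DEFS)
        assert rec.lengths["V1T1"] == pytest.approx(10.0)
        assert "T1T2" not in rec.lengths
        assert rec.missing["T1T2"] == ["T2"]
        assert rec.missing["V1T1T2V2"] == ["T2"]

    def test_exact_positions_reproduce_analytic_values(self):
        rec = measure_scan(POS, DEFS)
        assert rec.lengths["T1T2"] == pytest.approx(5.0, abs=1e-9)
        assert rec.areas["V1T1T2V2"] == pytest.approx(50.0, abs=1e-9)


def _record(values, scan_id="s", weeks=0.0):
    return MeasurementRecord(
        scan_id=scan_id, timepoint_weeks=weeks,
        lengths=dict(values.get("lengths", {})),
        areas=dict(values.get("areas", {})),
        angles=dict(values.get("angles", {})),
    )


class TestPrecisionSummary:
    def test_pooled_precision_is_mean_of_sample_sds(self):
        recs = [
            _record({"lengths": {"a": 10.0, "b": 5.0}}, "s1"),
            _record({"lengths": {"a": 11.0, "b": 5.0}}, "s2"),
            _record({"lengths": {"a": 12.0, "b": 5.0}}, "s3"),
        ]
        summ = precision_summary(recs)
        assert summ.table.loc["a", "sd"] == pytest.approx(1.0)  # sd([10,11,12], n-1)
        assert summ.table.loc["b", "sd"] == 0.0
        assert summ.pooled["lengths"] == pytest.approx(0.5)

    def test_identical_repeats_have_zero_precision(self):
        rec = {"lengths": {"a": 3.0}, "areas": {"q": 9.0}, "angles": {"extension": 12.0}}
        summ = precision_summary([_record(rec, f"s{i}") for i in range(4)])
        assert all(v == 0.0 for v in summ.pooled.values())

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(MarkerMorphError):
            precision_summary([_record({"lengths": {"a": 1.0}})])

    def test_mismatched_measurement_sets_rejected(self):
        with pytest.raises(StudyValidationError):
            precision_summary([
                _record({"lengths": {"a": 1.0}}, "s1"),
                _record({"lengths": {"b": 1.0}}, "s2"),
            ])


class TestLongitudinalSummary:
    def test_changes_are_final_minus_baseline(self):
        recs = [
            _record({"lengths": {"a": 10.0, "b": 20.0}}, "w0", weeks=0),
            _record({"lengths": {"a": 12.0, "b": 19.0}}, "w3", weeks=3),
            _record({"lengths": {"a": 15.0, "b": 27.0}}, "w26", weeks=26),
        ]
        summ = longitudinal_summary(recs)
        assert summ.changes == {"a": pytest.approx(5.0), "b": pytest.approx(7.0)}
        assert summ.mean == pytest.approx(6.0)
        assert summ.sd == pytest.approx(np.std([5, 7], ddof=1))
        assert (summ.baseline_weeks, summ.final_weeks) == (0, 26)

    def test_records_sorted_by_timepoint_not_input_order(self):
        recs = [
            _record({"lengths": {"a": 15.0}}, "w26", weeks=26),
            _record({"lengths": {"a": 10.0}}, "w0", weeks=0),
        ]
        assert longitudinal_summary(recs).changes["a"] == pytest.approx(5.0)

    def test_identical_records_give_zero_change(self):
        recs = [_record({"lengths": {"a": 4.0}}, "s1", 0),
                _record({"lengths": {"a": 4.0}}, "s2", 26)]
        summ = longitudinal_summary(recs)
        assert summ.mean == 0.0 and summ.sd == 0.0

    def test_name_subset_restricts_summary(self):
        recs = [
            _record({"lengths": {"a": 1.0, "b": 1.0}}, "w0", 0),
            _record({"lengths": {"a": 2.0, "b": 9.0}}, "w1", 1),
        ]
        summ = longitudinal_summary(recs, names=["a"])
        assert summ.changes == {"a": pytest.approx(1.0)}
        with pytest.raises(StudyValidationError):
            longitudinal_summary(recs, names=["zz"])
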