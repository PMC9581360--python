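import numpy as np
import pytest

from earmotion import (
    EarMotion,
    affine_dimension,
    classification_table,
    classify_motion,
    enumerate_motions,
    is_mirror_symmetric,
    orbit_points,
    phase_shifted_motion,
    satisfies_four_conditions,
)
from earmotion.kinematics import Pairing


class TestOrbitPoints:
    def test_static_motion_is_a_point(self):
        pts = orbit_points(EarMotion.from_pattern("0,0,0"), "left")
        assert np.allclose(pts, 0.0)
        assert affine_dimension(pts) == 0

    def test_circle_orbit(self):
        # left ear of [SIN, COS~, CONST~]: (C sin u, C cos u, C)
        m = EarMotion.from_pattern("SIN,COS~,CONST~", amplitude=15.0)
        pts = orbit_points(m, "left", 64)
        assert np.allclose(pts[:, 2], 15.0)
        radii = np.hypot(pts[:, 0], pts[:, 1])
        np.testing.assert_allclose(radii, 15.0, atol=1e-9)
        assert affine_dimension(pts) == 2

    def test_segment_orbit(self):
        # left ear of [0, COS~, CONST~]: {0} x [-C, C] x {C}
        m = EarMotion.from_pattern("0,COS~,CONST~", amplitude=15.0)
        pts = orbit_points(m, "left", 64)
        assert np.allclose(pts[:, 0], 0.0)
        assert np.allclose(pts[:, 2], 15.0)
        assert pts[:, 1].min() == pytest.approx(-15.0, abs=0.2)
        assert affine_dimension(pts) == 1

    def test_minimum_sample_count(self):
        with pytest.raises(ValueError):
            orbit_points(EarMotion.from_pattern("0,0,0"), "left", 8)


class TestAffineDimension:
    def test_known_dimensions(self):
        rng = np.random.default_rng(0)
        u = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        circle = np.stack([np.cos(u), np.sin(u), np.zeros_like(u)], axis=1)
        segment = np.stack([u, 2 * u, -u], axis=1)
        point = np.tile([1.0, 2.0, 3.0], (5, 1))
        cloud = rng.normal(size=(40, 3))
        assert affine_dimension(circle) == 2
        assert affine_dimension(segment) == 1
        assert affine_dimension(point) == 0
        assert affine_dimension(cloud) == 3

    def test_rotation_invariance(self):
        from earmotion import axis_rotation

        u = np.linspace(0, 2 * np.pi, 30, endpoint=False)
        circle = np.stack([np.cos(u), np.sin(u), np.zeros_like(u)], axis=1)
        rotated = circle @ axis_rotation("x", 37.0).T + np.array([1.0, -2.0, 0.5])
        assert affine_dimension(rotated) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            affine_dimension(np.empty((0, 3)))


class TestClassification:
    def test_two_circles_span_3d(self):
        c = classify_motion(EarMotion.from_pattern("SIN,COS~,CONST~"))
        assert c.dimension_pair == "3-2"
        assert c.orbit_dims == (2, 2)

    def test_two_parallel_segments_span_2d(self):
        c = classify_motion(EarMotion.from_pattern("0,COS~,CONST~"))
        assert c.dimension_pair == "2-1"

    def test_coplanar_orbits_fail_hull_condition(self):
        # both orbits of [SIN~, COS~, SIN~] lie in the plane psi = theta
        # (left) / psi = theta (right, both negated): hull is 2D
        assert not satisfies_four_conditions(
            EarMotion.from_pattern("SIN~,COS~,SIN~")
        )

    def test_showcase_motion_satisfies_all(self):
        assert satisfies_four_conditions(EarMotion.from_pattern("SIN,COS~,CONST~"))

    def test_classification_invariant_to_amplitude_and_sampling(self):
        for amp in (5.0, 15.0, 40.0):
            for n in (32, 256):
                c = classify_motion(
                    EarMotion.from_pattern("SIN,COS~,CONST~", amplitude=amp), n
                )
                assert c.dimension_pair == "3-2"
                assert c.satisfies_all


class TestCombinatorialCounts:
    def test_14_of_216_satisfy_all_four_conditions(self, all_216_motions):
        table = classification_table(all_216_motions)
        assert len(table) == 216
        assert int(table.satisfies_all.sum()) == 14

    def test_5_of_36_satisfy_first_three_conditions(self):
        table = classification_table(enumerate_motions(Pairing.COS_ANTI))
        assert len(table) == 36
        first3 = table.cond_hull_3d & table.cond_orbits_2d & table.cond_yaw_distinct
        assert int(first3.sum()) == 5

    def test_exactly_one_high_performer_is_mirror_symmetric(self):
        table = classification_table(enumerate_motions(Pairing.COS_ANTI))
        first3 = table.cond_hull_3d & table.cond_orbits_2d & table.cond_yaw_distinct
        winners = table[first3]
        assert int(winners.mirror_symmetric.sum()) == 1
        assert winners[winners.mirror_symmetric].pattern.item() == "SIN,COS~,CONST~"

    def test_counts_invariant_to_amplitude(self):
        for amp in (5.0, 30.0):
            table = classification_table(enumerate_motions(amplitude=amp))
            assert int(table.satisfies_all.sum()) == 14


class TestMirrorSymmetry:
    def test_sin_cosanti_constanti_is_mirror_symmetric(self):
        assert is_mirror_symmetric(EarMotion.from_pattern("SIN,COS~,CONST~"))

    def test_sinanti_variant_is_not(self):
        assert not is_mirror_symmetric(EarMotion.from_pattern("SIN~,COS~,CONST~"))


class TestPhaseShiftedMotions:
    def test_180_degrees_reproduces_all_antiphase_pattern(self):
        m = phase_shifted_motion(delta_phi=180.0)
        ref = EarMotion.from_pattern("CONST~,COS~,SIN~")
        ts = np.linspace(0, m.period, 33, endpoint=False)
        for side in ("left", "right"):
            for a, b in zip(m.angles(side, ts), ref.angles(side, ts)):
                np.testing.assert_allclose(a, b, atol=1e-9)

    def test_0_degrees_reproduces_inphase_pattern(self):
        m = phase_shifted_motion(delta_phi=0.0)
        ref = EarMotion.from_pattern("CONST~,COS,SIN")
        ts = np.linspace(0, m.period, 33, endpoint=False)
        for side in ("left", "right"):
            for a, b in zip(m.angles(side, ts), ref.angles(side, ts)):
                np.testing.assert_allclose(a, b, atol=1e-9)

    def test_orbits_are_circles_in_offset_planes(self):
        m = phase_shifted_motion(amplitude=15.0, delta_phi=90.0)
        left = orbit_points(m, "left", 64)
        right = orbit_points(m, "right", 64)
        assert np.allclose(left[:, 0], 15.0) and np.allclose(right[:, 0], -15.0)
        np.testing.assert_allclose(np.hypot(left[:, 1], left[:, 2]), 15.0, atol=1e-9)
        np.testing.assert_allclose(np.hypot(right[:, 1], right[:, 2]), 15.0, atol=1e-9)

    @pytest.mark.parametrize("dp,expected", [(0.0, False), (45.0, True),
                                             (90.0, True), (135.0, True),
                                             (180.0, True)])
    def test_four_conditions_vs_phase_offset(self, dp, expected):
        assert satisfies_four_conditions(phase_shifted_motion(delta_phi=dp)) is expected
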