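import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earmotion import (
    AngleFunctionPair,
    EarMotion,
    Pairing,
    axis_rotation,
    direction_from_angles,
    evaluate_pair,
    orientation_at,
    orientation_history,
)
from earmotion.kinematics import DEFAULT_PERIOD, direction_vector


class TestAxisRotation:
    def test_zero_angle_is_identity(self):
        for ax in "xyz":
            assert np.allclose(axis_rotation(ax, 0.0), np.eye(3), atol=1e-15)

    def test_quarter_turn_about_z(self):
        assert np.allclose(
            axis_rotation("z", 90.0) @ [1, 0, 0], [0, 1, 0], atol=1e-12
        )

    @given(st.floats(-720, 720), st.sampled_from("xyz"))
    @settings(deadline=None, max_examples=50)
    def test_special_orthogonal_and_invertible(self, angle, ax):
        R = axis_rotation(ax, angle)
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-12)
        assert np.allclose(R @ axis_rotation(ax, -angle), np.eye(3), atol=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            axis_rotation("w", 10.0)
        with pytest.raises(ValueError):
            axis_rotation("x", float("nan"))


class TestDirection:
    @pytest.mark.parametrize(
        "theta,phi,expected",
        [(0, 0, (1, 0, 0)), (90, 0, (0, 1, 0)), (0, 90, (0, 0, 1))],
    )
    def test_unit_vector_convention(self, theta, phi, expected):
        # elevation 90 is outside the validated domain; check the raw map
        n = direction_vector(theta, phi)
        assert np.allclose(n, expected, atol=1e-12)

    @given(st.floats(-60, 60), st.floats(-60, 60))
    @settings(deadline=None, max_examples=50)
    def test_unit_norm(self, theta, phi):
        d = direction_from_angles(theta, phi)
        assert np.isclose(np.linalg.norm(d.n), 1.0, atol=1e-12)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            direction_from_angles(61.0, 0.0)
        with pytest.raises(ValueError):
            direction_from_angles(0.0, -75.0)


class TestAngleFunctionPairs:
    def test_cos_antiphase_values(self):
        pair = AngleFunctionPair(Pairing.COS_ANTI, amplitude=15.0)
        left, right = evaluate_pair(pair, 0.0)
        assert left == pytest.approx(15.0)
        assert right == pytest.approx(-15.0)

    def test_const_antiphase_is_time_independent(self):
        pair = AngleFunctionPair(Pairing.CONST_ANTI, amplitude=15.0)
        for t in (0.0, 0.01, 0.33):
            left, right = evaluate_pair(pair, t)
            assert (left, right) == (15.0, -15.0)

    def test_sin_pairings_start_at_zero(self):
        for p in (Pairing.SIN, Pairing.SIN_ANTI):
            left, right = evaluate_pair(AngleFunctionPair(p), 0.0)
            assert left == pytest.approx(0.0)
            assert right == pytest.approx(0.0)

    def test_antiphase_mirror_property(self):
        ts = np.linspace(0, DEFAULT_PERIOD, 37)
        for p in (Pairing.CONST_ANTI, Pairing.SIN_ANTI, Pairing.COS_ANTI):
            pair = AngleFunctionPair(p)
            np.testing.assert_allclose(pair.left(ts), -pair.right(ts), atol=1e-12)

    def test_periodicity(self):
        rng = np.random.default_rng(7)
        ts = rng.uniform(0, 1, 16)
        for p in Pairing:
            pair = AngleFunctionPair(p)
            np.testing.assert_allclose(
                pair.left(ts + pair.period), pair.left(ts), atol=1e-9
            )

    def test_phase_offset_applies_to_right_ear_only(self):
        pair = AngleFunctionPair(Pairing.COS, phase_offset=180.0)
        left, right = evaluate_pair(pair, 0.0)
        assert left == pytest.approx(pair.amplitude)
        assert right == pytest.approx(-pair.amplitude)

    def test_unknown_pairing_rejected(self):
        with pytest.raises(ValueError):
            EarMotion.from_pattern("SIN,WOBBLE,COS~")


class TestOrientation:
    def test_all_zero_motion_gives_identity(self):
        m = EarMotion.from_pattern("0,0,0")
        for t in (0.0, 0.01, 0.05):
            for side in ("left", "right"):
                assert np.allclose(orientation_at(m, side, t), np.eye(3), atol=1e-15)

    def test_matches_explicit_matrix_product(self):
        # left ear of [SIN, COS~, CONST~] at t=0: psi=0, phi=15, theta=15
        m = EarMotion.from_pattern("SIN,COS~,CONST~", amplitude=15.0)
        expected = (
            axis_rotation("z", 15.0)
            @ axis_rotation("y", -15.0)
            @ axis_rotation("x", 0.0)
        )
        assert np.allclose(orientation_at(m, "left", 0.0), expected, atol=1e-12)

    def test_rotation_group_membership_all_patterns(self, all_216_motions):
        rng = np.random.default_rng(3)
        ts = rng.uniform(0, 0.2, 4)
        for m in all_216_motions:
            for side in ("left", "right"):
                L = orientation_history(m, side, ts)
                np.testing.assert_allclose(
                    np.swapaxes(L, 1, 2) @ L, np.broadcast_to(np.eye(3), L.shape),
                    atol=1e-12,
                )
                np.testing.assert_allclose(np.linalg.det(L), 1.0, atol=1e-12)

    def test_orientation_periodicity(self):
        m = EarMotion.from_pattern("SIN~,COS~,CONST~")
        rng = np.random.default_rng(11)
        ts = rng.uniform(0, 0.5, 8)
        np.testing.assert_allclose(
            orientation_history(m, "left", ts + m.period),
            orientation_history(m, "left", ts),
            atol=1e-12,
        )


class TestPatternParsing:
    def test_round_trip(self):
        for pat in ("0,CONST~,CONST~", "SIN,COS~,SIN~", "COS,0,SIN~"):
            assert EarMotion.from_pattern(pat).pattern == pat

    def test_shared_frequency_enforced(self):
        with pytest.raises(ValueError):
            EarMotion(
                roll=AngleFunctionPair(Pairing.SIN, frequency=10.0),
                pitch=AngleFunctionPair(Pairing.COS, frequency=20.0),
                yaw=AngleFunctionPair(Pairing.ZERO, frequency=10.0),
            )
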