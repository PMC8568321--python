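import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gravipoint.errors import SegmentationError, ValidationError
from gravipoint.generate import beta_position_profile, minimum_jerk_position, simulate_movement
from gravipoint.kinematics import (
    apply_accuracy_filter,
    curvature_max_x,
    endpoint_deviation,
    extract_features,
    movement_duration,
    rtpv,
    velocity_profile,
)
from gravipoint.preprocess import SegmentedMovement, segment_movement

from conftest import noise_free_params


def _segment(onset=10.0, offset=10.55):
    t = np.linspace(onset, offset, 56)
    traj = np.column_stack([np.zeros(56), np.linspace(0, 100, 56), np.zeros(56)])
    return SegmentedMovement(onset, offset, t, traj, (0.0, 100.0), gaps=None)


class TestDuration:
    def test_release_to_press_interval(self):
        assert movement_duration(_segment()) == pytest.approx(0.55)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(SegmentationError):
            SegmentedMovement(10.0, 10.0, np.zeros(2), np.zeros((2, 3)), (0, 0), None)


class TestEndpointDeviation:
    @pytest.mark.parametrize(
        "press_y, direction, signed, overshoot",
        [
            (125.0, "up", 5.0, True),     # above an upper target: overshot
            (120.0, "up", 0.0, None),     # dead center
            (115.0, "up", -5.0, False),   # below an upper target: undershot
            (-115.0, "down", 5.0, False), # above a lower target: undershot
            (-125.0, "down", -5.0, True), # below a lower target: overshot
        ],
    )
    def test_sign_and_overshoot_semantics(self, press_y, direction, signed, overshoot):
        s, a, o = endpoint_deviation((0.0, press_y), direction, 12.0)
        assert s == pytest.approx(signed)
        assert a == pytest.approx(abs(signed))
        assert o is overshoot

    def test_accuracy_filter_boundary(self):
        df = pd.DataFrame({"absolute_deviation_mm": [5.0, 15.0, 20.0, 21.0, 30.0]})
        out = apply_accuracy_filter(df)
        assert list(out["retained"]) == [True, True, True, False, False]

    def test_accuracy_filter_strict_inequality(self):
        df = pd.DataFrame({"absolute_deviation_mm": [20.0001]})
        assert not apply_accuracy_filter(df)["retained"].iloc[0]


class TestVelocityAndRtpv:
    def test_linear_motion_constant_speed(self):
        t = np.linspace(0, 1, 101)
        traj = np.column_stack([np.zeros(101), 100 * t, np.zeros(101)])
        speed = velocity_profile(traj, t)
        np.testing.assert_allclose(speed[1:-1], 100.0, rtol=1e-9)

    def test_stationary_trajectory_zero_speed(self):
        t = np.linspace(0, 1, 50)
        speed = velocity_profile(np.ones((50, 3)), t)
        np.testing.assert_allclose(speed, 0.0, atol=1e-12)

    def test_minimum_jerk_peak_speed_analytic(self):
        A, T = 120.0, 0.6
        t = np.linspace(0, T, 2001)
        traj = np.column_stack(
            [np.zeros_like(t), A * minimum_jerk_position(t / T), np.zeros_like(t)]
        )
        speed = velocity_profile(traj, t)
        assert speed.max() == pytest.approx(1.875 * A / T, rel=1e-4)

    def test_symmetric_triangular_profile_rtpv_half(self):
        t = np.linspace(0, 1, 101)
        speed = 1 - np.abs(2 * t - 1)
        assert rtpv(speed, t, 0.0, 1.0) == pytest.approx(0.5)

    def test_peak_position_brute_force(self):
        t = np.linspace(0, 1, 100)
        speed = np.zeros(100)
        speed[44] = 1.0
        # brute-force oracle: scan for the maximum
        best = max(range(100), key=lambda i: speed[i])
        assert rtpv(speed, t, 0.0, 1.0) == pytest.approx(t[best], abs=1e-12)
        assert rtpv(speed, t, 0.0, 1.0) == pytest.approx(44 / 99)

    def test_minimum_jerk_rtpv_is_half(self):
        T = 0.5
        t = np.linspace(0, T, 501)
        traj = np.column_stack(
            [np.zeros_like(t), 100 * minimum_jerk_position(t / T), np.zeros_like(t)]
        )
        speed = velocity_profile(traj, t)
        assert rtpv(speed, t, 0.0, T) == pytest.approx(0.5, abs=1.0 / 500)

    def test_flat_zero_profile_undefined(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValidationError):
            rtpv(np.zeros(10), t, 0.0, 1.0)

    @given(
        time_scale=st.floats(0.1, 10.0),
        amp_scale=st.floats(0.1, 10.0),
    )
    def test_rtpv_invariant_to_rescaling(self, time_scale, amp_scale):
        t = np.linspace(0, 1, 200)
        speed = beta_position_profile(t, 0.44)  # any fixed asymmetric shape
        speed = np.gradient(speed, t)
        r0 = rtpv(speed, t, 0.0, 1.0)
        r1 = rtpv(amp_scale * speed, time_scale * t, 0.0, time_scale)
        assert r1 == pytest.approx(r0, abs=1e-12)


class TestCurvature:
    def test_straight_vertical_line_zero(self):
        t = np.linspace(0, 1, 100)
        traj = np.column_stack([np.zeros(100), 100 * t, np.zeros(100)])
        assert curvature_max_x(traj) == pytest.approx(0.0, abs=1e-12)

    def test_half_sine_bulge_toward_trunk(self):
        tau = np.linspace(0, 1, 1000)
        traj = np.column_stack([-7.0 * np.sin(np.pi * tau), 120 * tau, np.zeros(1000)])
        # dense-grid oracle: the largest |x - chord_x| with chord x = 0
        oracle = traj[np.argmax(np.abs(traj[:, 0])), 0]
        assert curvature_max_x(traj) == pytest.approx(oracle)
        assert curvature_max_x(traj) == pytest.approx(-7.0, abs=1e-4)

    def test_oblique_chord_without_bulge_is_zero(self):
        tau = np.linspace(0, 1, 100)
        traj = np.column_stack([30 * tau, 100 * tau, np.zeros(100)])
        assert curvature_max_x(traj) == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_rigid_vertical_translation(self):
        rng = np.random.default_rng(1)
        tau = np.linspace(0, 1, 300)
        traj = np.column_stack(
            [5 * np.sin(2 * np.pi * tau), 150 * tau + 3 * np.sin(np.pi * tau), np.zeros(300)]
        )
        shifted = traj + np.array([0.0, 42.0, 0.0])
        assert curvature_max_x(shifted) == pytest.approx(curvature_max_x(traj))

    def test_degenerate_chord_rejected(self):
        with pytest.raises(ValidationError):
            curvature_max_x(np.zeros((10, 3)))


class TestGeneratorRoundTrip:
    @pytest.mark.parametrize("gravity,direction", [("normo", "up"), ("micro", "up"), ("hyper", "down")])
    def test_noise_free_feature_recovery(self, gravity, direction, clean_params):
        trial, truth = simulate_movement(gravity, False, direction, 16.0, clean_params, seed=0)
        seg = segment_movement(trial)
        f = extract_features(trial, seg)
        assert f.duration_s == pytest.approx(truth["duration_s"], abs=1e-9)
        assert f.signed_deviation_mm == pytest.approx(truth["signed_deviation_mm"], abs=1e-9)
        # timing error at most one marker sample
        assert abs(f.rtpv - truth["rtpv"]) * f.duration_s <= 1.0 / 100.0 + 1e-9
        # curvature recovery is limited by the 10 Hz filter's edge transient
        # around onset/offset (a few percent of the bulge), not by noise
        assert f.curvature_mm == pytest.approx(truth["curvature_mm"], rel=0.05, abs=0.15)

    def test_overshoot_frequency_half_on_zero_bias_data(self):
        params = noise_free_params(
            endpoint_noise_sd_mm=4.0,
            endpoint_bias_mm={k: 0.0 for k in noise_free_params().endpoint_bias_mm},
        )
        n = 200
        over = 0
        for s in range(n):
            _, truth = simulate_movement("normo", False, "up", 12.0, params, seed=s)
            over += truth["signed_deviation_mm"] > 0
        p = over / n
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / n)
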