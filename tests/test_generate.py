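import numpy as np
import pytest

from gravipoint.errors import ValidationError
from gravipoint.flight import make_flight_profile
from gravipoint.generate import (
    GeneratorParams,
    beta_position_profile,
    emg_burst_envelope,
    inject_defects,
    make_target_sequence,
    minimum_jerk_position,
    simulate_emg,
    simulate_experiment,
    simulate_movement,
)
from gravipoint.io import DIRECTIONS, TARGET_DISTANCES_CM

from conftest import noise_free_params


class TestFlightProfile:
    def test_ten_parabolas_repeat_three_measured_phases(self):
        profile = make_flight_profile(10, rest_s=0.001)
        for p in range(1, 11):
            phases = profile.phase[profile.parabola == p]
            order = list(dict.fromkeys(phases))
            assert order[:3] == ["steady_1g", "pullup_2g", "weightless_0g"]
        assert len(np.unique(profile.parabola)) == 10

    def test_noiseless_weightless_phase_is_exactly_zero_g(self):
        profile = make_flight_profile(1)
        assert np.all(profile.gravity[profile.phase == "weightless_0g"] == 0.0)

    def test_noisy_phase_means_within_standard_error_bound(self):
        sd = 0.02
        profile = make_flight_profile(1, gravity_noise_sd=sd, seed=0)
        for phase, nominal in [("steady_1g", 1.0), ("pullup_2g", 1.8), ("weightless_0g", 0.0)]:
            g = profile.gravity[profile.phase == phase]
            assert abs(g.mean() - nominal) < 3 * sd / np.sqrt(len(g))

    def test_zero_parabolas_rejected(self):
        with pytest.raises(ValidationError):
            make_flight_profile(0)


class TestTargetSequence:
    @pytest.mark.parametrize("n_reps", [1, 2])
    def test_every_target_equally_represented(self, n_reps):
        seq = make_target_sequence(n_reps, seed=3)
        assert len(seq) == 14 * n_reps
        for d in DIRECTIONS:
            for dist in TARGET_DISTANCES_CM:
                assert seq.count((d, dist)) == n_reps
        dists_up = {dist for d, dist in seq if d == "up"}
        assert len(dists_up) == 7

    def test_deterministic_given_seed(self):
        assert make_target_sequence(2, seed=9) == make_target_sequence(2, seed=9)

    def test_no_long_runs(self):
        for seed in range(10):
            seq = make_target_sequence(3, seed=seed)
            run = 1
            for a, b in zip(seq, seq[1:]):
                run = run + 1 if a == b else 1
                assert run <= 3


class TestSimulateMovement:
    def test_zero_curvature_yields_vertical_path(self):
        params = noise_free_params(
            curvature_mm={k: 0.0 for k in GeneratorParams().curvature_mm}
        )
        trial, _ = simulate_movement("normo", False, "up", 12.0, params, seed=0)
        assert np.nanmax(np.abs(trial.marker_xyz[:, 0])) < 1e-9

    def test_duration_ratio_matches_multiplier_exactly(self):
        params = noise_free_params()
        t_micro, _ = simulate_movement("micro", False, "up", 12.0, params, seed=0)
        t_normo, _ = simulate_movement("normo", False, "up", 12.0, params, seed=0)

        def dur(t):
            r = next(e.time_s for e in t.touch_events if e.kind == "release")
            p = next(e.time_s for e in t.touch_events if e.kind == "press" and e.time_s > r)
            return p - r

        assert dur(t_micro) / dur(t_normo) == pytest.approx(1.30, abs=1e-9)

    def test_endpoint_bias_recovered_by_monte_carlo(self):
        params = GeneratorParams()
        devs = [
            simulate_movement("hyper", False, "up", 12.0, params, seed=s)[1][
                "signed_deviation_mm"
            ]
            for s in range(100)
        ]
        se = np.std(devs) / np.sqrt(len(devs))
        assert abs(np.mean(devs) - (-6.0)) < 3 * se + 0.5

    def test_press_coordinate_equals_trajectory_endpoint(self):
        params = noise_free_params()
        trial, _ = simulate_movement("normo", False, "down", 16.0, params, seed=0)
        press = [e for e in trial.touch_events if e.kind == "press"][-1]
        end = trial.marker_xyz[trial.t_markers >= press.time_s][0]
        assert press.x_mm == pytest.approx(end[0], abs=1e-9)
        assert press.y_mm == pytest.approx(end[1], abs=1e-9)

    def test_full_compensation_identical_in_law_to_normogravity(self):
        params = noise_free_params(lambda_attenuation=0.0)
        comp, _ = simulate_movement("micro", True, "up", 12.0, params, seed=11)
        normo, _ = simulate_movement("normo", False, "up", 12.0, params, seed=11)
        np.testing.assert_allclose(comp.marker_xyz, normo.marker_xyz, atol=1e-12)


class TestSimulateEmg:
    def test_zero_effective_gravity_silences_sensitive_muscle(self):
        params = noise_free_params()
        trial, _ = simulate_movement("micro", False, "up", 12.0, params, seed=0)
        emg = simulate_emg(trial, params, seed=1, g_eff=0.0)
        assert np.abs(emg[:, 0]).max() == 0.0  # deltoid anterior

    def test_burst_envelope_iemg_scales_with_gravity(self):
        t = np.arange(0, 1.0, 0.001)
        lo = emg_burst_envelope(t, 0.2, 0.8, integral_mv_s=1.0)
        hi = emg_burst_envelope(t, 0.2, 0.8, integral_mv_s=1.8)
        assert np.trapezoid(hi, t) / np.trapezoid(lo, t) == pytest.approx(1.8)

    def test_pectoralis_iemg_flat_across_gravities(self):
        params = GeneratorParams()
        means = {}
        for g, g_eff in [("micro", 0.0), ("normo", 1.0), ("hyper", 1.8)]:
            vals = []
            for s in range(30):
                trial, _ = simulate_movement(g, False, "up", 12.0, params, seed=s)
                emg = simulate_emg(trial, params, seed=1000 + s, g_eff=g_eff)
                vals.append(np.abs(emg[:, 3]).mean())
            means[g] = (np.mean(vals), np.std(vals) / np.sqrt(len(vals)))
        for g in ("micro", "hyper"):
            assert abs(means[g][0] - means["normo"][0]) < 4 * (
                means[g][1] + means["normo"][1]
            )


class TestInjectDefects:
    def test_planted_defects_listed_in_ground_truth(self, small_experiment):
        trials, _ = small_experiment
        out, truth = inject_defects(trials, {"missing_run": 1}, seed=3)
        assert list(truth["defect"]) == ["missing_run"]
        stem = truth["stem"].iloc[0]
        bad = next(t for t in out if t.stem == stem)
        gap = np.isnan(bad.marker_xyz).any(axis=1)
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, gap, 0])))[::2]
        assert runs.max() >= 6

    def test_no_defects_empty_ground_truth(self, small_experiment):
        trials, _ = small_experiment
        out, truth = inject_defects(trials, {}, seed=0)
        assert truth.empty and len(out) == len(trials)

    def test_unknown_defect_type_rejected(self, small_experiment):
        trials, _ = small_experiment
        with pytest.raises(ValidationError, match="unknown defect"):
            inject_defects(trials, {"cosmic_rays": 1}, seed=0)


class TestExperimentDesign:
    def test_balanced_design_covers_every_cell(self, small_experiment):
        trials, _ = small_experiment
        cells = {
            (t.gravity_condition, t.compensation, t.direction, t.target_distance_cm)
            for t in trials
        }
        assert len(cells) == 3 * 2 * 2 * 7

    def test_ground_truth_row_per_trial(self, small_experiment):
        trials, truth = small_experiment
        assert len(truth) == len(trials)
        assert set(truth["stem"]) == {t.stem for t in trials}


class TestProfiles:
    def test_minimum_jerk_endpoints_and_midpoint(self):
        tau = np.array([0.0, 0.5, 1.0])
        np.testing.assert_allclose(minimum_jerk_position(tau), [0.0, 0.5, 1.0])

    def test_beta_profile_is_monotone_displacement(self):
        tau = np.linspace(0, 1, 500)
        pos = beta_position_profile(tau, rtpv=0.44)
        assert pos[0] == 0.0 and pos[-1] == pytest.approx(1.0)
        assert np.all(np.diff(pos) >= 0)

    def test_beta_profile_speed_peaks_at_requested_rtpv(self):
        tau = np.linspace(0, 1, 20001)
        pos = beta_position_profile(tau, rtpv=0.44)
        speed = np.gradient(pos, tau)
        assert tau[np.argmax(speed)] == pytest.approx(0.44, abs=2e-3)
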