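import numpy as np
import pytest
from scipy.signal import butter, sosfreqz

from gravipoint.config import QCThresholds
from gravipoint.errors import SegmentationError, ValidationError
from gravipoint.generate import GeneratorParams, simulate_movement
from gravipoint.io import TouchEvent
from gravipoint.preprocess import (
    interpolate_gaps,
    lowpass_markers,
    qc_dataset,
    qc_trial,
    segment_movement,
)

from conftest import noise_free_params


class TestInterpolateGaps:
    def test_single_gap_linear_midpoint(self):
        filled, meta = interpolate_gaps(np.array([10.0, np.nan, 12.0]))
        assert filled[1] == pytest.approx(11.0)
        assert meta.runs == [(1, 1)]

    def test_gap_free_series_unchanged(self):
        x = np.arange(10.0)
        filled, meta = interpolate_gaps(x)
        np.testing.assert_array_equal(filled, x)
        assert meta.runs == [] and meta.max_run == 0

    def test_six_sample_gap_filled_with_metadata(self):
        x = np.linspace(0, 20, 21)
        x[5:11] = np.nan
        filled, meta = interpolate_gaps(x)
        assert not np.isnan(filled).any()
        np.testing.assert_allclose(filled, np.linspace(0, 20, 21))
        assert meta.max_run == 6

    def test_leading_gap_flagged_not_extrapolated(self):
        x = np.array([np.nan, 1.0, 2.0])
        filled, meta = interpolate_gaps(x)
        assert meta.leading_or_trailing
        assert np.isnan(filled[0])


class TestLowpass:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.7)
        np.testing.assert_allclose(lowpass_markers(x), x, atol=1e-9)

    def test_symmetric_pulse_peak_not_shifted(self):
        x = np.zeros(301)
        x[150] = 1.0
        y = lowpass_markers(x)
        assert int(np.argmax(y)) == 150

    def test_cutoff_gain_matches_analytic_double_pass(self):
        # forward-backward 2nd-order Butterworth: |H|^2 at cutoff = 1/2
        fs, f0 = 100.0, 10.0
        sos = butter(2, f0, fs=fs, output="sos")
        w, h = sosfreqz(sos, worN=[2 * np.pi * f0 / fs])
        analytic = float(np.abs(h[0]) ** 2)
        assert analytic == pytest.approx(0.5, abs=1e-6)
        t = np.arange(3000) / fs
        y = lowpass_markers(np.sin(2 * np.pi * f0 * t))
        measured = np.sqrt(2 * np.mean(y[1000:2000] ** 2))  # RMS amplitude
        assert measured == pytest.approx(analytic, abs=0.01)

    def test_zero_phase_on_broadband_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        y = lowpass_markers(x)
        lags = np.arange(-20, 21)
        xc = [np.dot(x[20:-20], y[20 + k : len(y) - 20 + k]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            lowpass_markers(np.zeros(5))


class TestSegmentMovement:
    def test_onset_offset_from_touch_events(self, clean_params):
        trial, truth = simulate_movement("normo", False, "up", 12.0, clean_params, seed=0)
        seg = segment_movement(trial)
        assert seg.offset_s - seg.onset_s == pytest.approx(truth["duration_s"], abs=1e-9)
        assert seg.press_xy_mm[1] == pytest.approx(
            120.0 + truth["signed_deviation_mm"], abs=1e-9
        )

    def test_consecutive_presses_rejected(self, clean_params):
        trial, _ = simulate_movement("normo", False, "up", 12.0, clean_params, seed=0)
        trial.touch_events = [
            TouchEvent(0.05, "press", 0, 0),
            TouchEvent(0.30, "press", 0, 0),
        ]
        with pytest.raises(SegmentationError, match="consecutive"):
            segment_movement(trial)

    def test_missing_release_rejected(self, clean_params):
        trial, _ = simulate_movement("normo", False, "up", 12.0, clean_params, seed=0)
        trial.touch_events = [TouchEvent(0.05, "press", 0, 0)]
        with pytest.raises(SegmentationError, match="release"):
            segment_movement(trial)


class TestQCRules:
    def test_clean_trial_passes_with_empty_reasons(self, clean_params):
        trial, _ = simulate_movement("normo", False, "up", 12.0, clean_params, seed=0)
        report = qc_trial(trial)
        assert report.passed and report.reasons == set()

    def test_reference_sd_exactly_at_threshold_passes(self, clean_params):
        trial, _ = simulate_movement("normo", False, "up", 12.0, clean_params, seed=0)
        n = len(trial.t_markers)
        trial.reference_markers = trial.reference_markers.copy()
        # alternating +/-4 mm has SD exactly 4.0 (rule is strict 'exceeded')
        trial.reference_markers[:, 0, 0] = 4.0 * (-1.0) ** np.arange(n)
        report = qc_trial(trial)
        assert "reference_drift" not in report.reasons
        trial.reference_markers[:, 0, 0] *= 1.01
        report = qc_trial(trial)
        assert "reference_drift" in report.reasons

    def test_missing_run_boundary_five_passes_six_fails(self, clean_params):
        for run, should_fail in [(5, False), (6, True)]:
            trial, _ = simulate_movement("normo", False, "up", 12.0, clean_params, seed=0)
            trial.marker_xyz = trial.marker_xyz.copy()
            trial.marker_xyz[60 : 60 + run] = np.nan
            report = qc_trial(trial)
            assert ("missing_run" in report.reasons) == should_fail

    def test_gravity_change_during_movement_fails(self, clean_params):
        trial, _ = simulate_movement("micro", False, "up", 12.0, clean_params, seed=0)
        mid = len(trial.t_emg) // 2
        trial.gravity_trace = trial.gravity_trace.copy()
        trial.gravity_trace[mid:] = 1.0
        report = qc_trial(trial)
        assert "gravity_change" in report.reasons

    def test_bad_start_outside_circle(self, clean_params):
        trial, _ = simulate_movement("normo", False, "up", 12.0, clean_params, seed=0)
        trial.touch_events = [
            TouchEvent(e.time_s, e.kind, e.x_mm + 31.0, e.y_mm)
            if e.kind == "release"
            else e
            for e in trial.touch_events
        ]
        report = qc_trial(trial)
        assert "bad_start" in report.reasons

    def test_duration_invariant_to_marker_processing(self, clean_params):
        trial, truth = simulate_movement("normo", False, "up", 12.0, clean_params, seed=0)
        seg1 = segment_movement(trial, cutoff_hz=10.0)
        seg2 = segment_movement(trial, cutoff_hz=3.0)
        assert seg1.offset_s - seg1.onset_s == seg2.offset_s - seg2.onset_s


class TestQCGroundTruthRecovery:
    def test_perfect_sensitivity_and_specificity(self, defect_fixture):
        trials, truth = defect_fixture
        report = qc_dataset(trials)
        merged = report.merge(truth, on="stem", how="left").fillna({"defect": ""})
        planted = merged[merged["defect"] != ""]
        clean = merged[merged["defect"] == ""]
        assert len(planted) >= 50 and len(clean) >= 190
        assert (~planted["passed"]).all()          # sensitivity = 1
        assert clean["passed"].all()               # specificity = 1

    def test_planted_defect_type_appears_in_reasons(self, defect_fixture):
        trials, truth = defect_fixture
        report = qc_dataset(trials)
        merged = report.merge(truth, on="stem")
        for row in merged.itertuples():
            assert row.defect in str(row.reasons)
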