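import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gravipoint.generate import (
    GeneratorParams,
    inject_defects,
    simulate_experiment,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def noise_free_params(**overrides) -> GeneratorParams:
    base = dict(
        duration_noise_sd_s=0.0,
        endpoint_noise_sd_mm=0.0,
        curvature_noise_sd_mm=0.0,
        marker_noise_sd_mm=0.0,
        dropout_rate=0.0,
        gravity_noise_sd=0.0,
        touch_jitter_x_mm=0.0,
        reference_noise_sd_mm=0.0,
        emg_trial_cv=0.0,
        emg_noise_floor_mv=0.0,
        participant_duration_sd_s=0.0,
        participant_bias_sd_mm=0.0,
        participant_curvature_sd_mm=0.0,
        participant_emg_sd_rel=0.0,
    )
    base.update(overrides)
    return GeneratorParams(**base)


@pytest.fixture(scope="session")
def clean_params():
    return noise_free_params()


@pytest.fixture(scope="session")
def small_experiment():
    """One participant, two parabolas (one compensated): 84 balanced trials."""
    trials, truth = simulate_experiment(
        GeneratorParams(), n_participants=1, n_parabolas=2, seed=5
    )
    return trials, truth


@pytest.fixture(scope="session")
def defect_fixture():
    """252 trials, 56 with planted defects (7 per type), plus ground truth."""
    trials, _ = simulate_experiment(
        GeneratorParams(), n_participants=3, n_parabolas=2, seed=5
    )
    spec = {
        kind: 7
        for kind in (
            "gravity_change",
            "hand_gravity_change",
            "reference_drift",
            "missing_run",
            "marker_jump",
            "bad_start",
            "opposite_direction",
            "abnormal_trajectory",
        )
    }
    corrupted, truth = inject_defects(trials, spec, seed=7)
    return corrupted, truth
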