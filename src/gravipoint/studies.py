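"""Simulation studies validating the statistical stage against generator truth.

These run many synthetic experiments through :func:`gravipoint.stats.fit_lmm`
and :func:`gravipoint.stats.planned_contrasts` to measure operating
characteristics: type-I error of the gravity main effect under the null,
power for the configured microgravity duration effect, and the rate at
which full compensation (lambda = 0) reproduces the headline contrast
pattern (gravity effects significant, compensated conditions
indistinguishable from normogravity).

Experiments are drawn with :func:`gravipoint.generate.simulate_feature_table`,
the distribution-level shortcut that shares its generative model with the
trajectory simulator.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .generate import GeneratorParams, simulate_feature_table
from .io import DIRECTIONS, GRAVITY_CONDITIONS, TARGET_DISTANCES_CM
from .stats import aggregate, fit_lmm, planned_contrasts


def null_cell_table(
    n_participants: int = 9,
    participant_sd: float = 0.05,
    noise_sd: float = 0.04,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Aggregated-cell data with no condition effects (pure participant + noise)."""
    rng = rng or np.random.default_rng()
    rows = []
    for p in range(n_participants):
        b = rng.normal(0.0, participant_sd)
        for g in GRAVITY_CONDITIONS:
            for c in (False, True):
                for dist in TARGET_DISTANCES_CM:
                    rows.append(
                        (f"S{p + 1:02d}", "up", g, c, dist, b + rng.normal(0.0, noise_sd))
                    )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "direction", "gravity_condition",
                 "compensation", "target_distance_cm", "y"],
    )


def type1_error_rate(
    n_sims: int = 1000,
    n_participants: int = 9,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the gravity main effect on null data."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        cells = null_cell_table(n_participants, rng=rng)
        fit = fit_lmm(cells, "y", direction="up")
        p = fit.effects.set_index("term").loc["C(gravity_condition)", "p"]
        hits += p < alpha
    return hits / n_sims


def power_0g_duration(
    n_sims: int = 200,
    params: GeneratorParams | None = None,
    n_participants: int = 9,
    n_reps_per_cell: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Detection rate of the gravity main effect on upward movement duration.

    The alternative is the generator default: microgravity upward movements
    1.30x longer than normogravity at the default noise levels.
    """
    params = params or GeneratorParams()
    ss = np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(n_sims):
        sim_seed = int(child.generate_state(1)[0] % (2**31))
        feats = simulate_feature_table(params, n_participants, n_reps_per_cell, sim_seed)
        cells = aggregate(feats, ["duration_s"])
        fit = fit_lmm(cells, "duration_s", direction="up")
        p = fit.effects.set_index("term").loc["C(gravity_condition)", "p"]
        hits += p < alpha
    return hits / n_sims


def compensation_pattern_rate(
    n_sims: int = 50,
    params: GeneratorParams | None = None,
    n_participants: int = 9,
    n_reps_per_cell: int = 5,
    seed: int = 0,
    direction: str = "up",
    response: str = "duration_s",
) -> float:
    """Rate at which full compensation reproduces the headline contrast pattern.

    With lambda = 0 (compensation fully restores normogravity statistics),
    a run counts as reproducing the pattern when 1g-0g and 1g-2g are
    significant after Bonferroni while 1g-0gC and 1g-2gC are not.
    """
    params = replace(params or GeneratorParams(), lambda_attenuation=0.0)
    ss = np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(n_sims):
        sim_seed = int(child.generate_state(1)[0] % (2**31))
        feats = simulate_feature_table(params, n_participants, n_reps_per_cell, sim_seed)
        cells = aggregate(feats, [response])
        fit = fit_lmm(cells, response, direction=direction)
        con = planned_contrasts(fit).set_index("comparison")
        ok = (
            con.loc["1g-0g", "significant"]
            and con.loc["1g-2g", "significant"]
            and not con.loc["1g-0gC", "significant"]
            and not con.loc["1g-2gC", "significant"]
        )
        hits += bool(ok)
    return hits / n_sims


def recover_condition_truth(
    n_participants: int = 9,
    n_reps_per_cell: int = 5,
    seed: int = 0,
    params: GeneratorParams | None = None,
) -> pd.DataFrame:
    """Condition-mean estimates vs generator truth from one fast-path experiment.

    Returns one row per (gravity, direction) with the estimated uncompensated
    duration multiplier, endpoint bias, and curvature next to the configured
    truth, plus the standard error of each estimate.
    """
    params = params or GeneratorParams()
    feats = simulate_feature_table(params, n_participants, n_reps_per_cell, seed)
    rows = []
    base = feats[(feats.gravity_condition == "normo") & (~feats.compensation)]
    for direction in DIRECTIONS:
        b = base[base.direction == direction]
        base_dur = b.duration_s.mean()
        for gravity in GRAVITY_CONDITIONS:
            sel = feats[
                (feats.gravity_condition == gravity)
                & (~feats.compensation)
                & (feats.direction == direction)
            ]
            n = len(sel)
            rows.append(
                {
                    "gravity": gravity,
                    "direction": direction,
                    "duration_mult_est": sel.duration_s.mean() / base_dur,
                    "duration_mult_true": params.duration_multipliers[(gravity, direction)],
                    "bias_est_mm": sel.signed_deviation_mm.mean(),
                    "bias_true_mm": params.endpoint_bias_mm[(gravity, direction)],
                    "bias_se_mm": sel.signed_deviation_mm.std() / np.sqrt(n),
                    "curvature_est_mm": sel.curvature_mm.mean(),
                    "curvature_true_mm": params.curvature_mm[(gravity, direction)],
                    "curvature_se_mm": sel.curvature_mm.std() / np.sqrt(n),
                }
            )
    return pd.DataFrame(rows)
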