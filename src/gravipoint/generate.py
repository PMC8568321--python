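"""Synthetic parabolic-flight pointing experiments.

The generator emulates the statistical structure the analysis stages assume:
per-trial stylus trajectories (beta-shaped speed profile, so the relative
time to peak velocity is settable), touchscreen events, four-channel EMG,
ambient/hand gravity traces, condition-dependent effect sizes, participant
random effects, and planted quality-control defects with ground-truth
labels.

Gravity effects enter as multiplicative duration factors and additive
endpoint-bias / trajectory-curvature offsets relative to normogravity.
Local compensation attenuates every gravity-effect delta by a factor
``lambda`` (1 = no benefit, 0 = full restoration of normogravity
statistics); behavioral improvement in flight was real but incomplete, so
the default is intermediate.  No group-level effect sizes were published
with raw data, so the default magnitudes are plausible placeholders chosen
to match the reported effect *directions* (longer upward movements in 0 g,
shorter in 2 g, upward undershoot in 2 g, curvature shifted toward the trunk
for upward 0 g movements, integrated EMG scaling with wrist gravity except
for the pectoralis).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .compensation import DEFAULT_COMPENSATED_PARABOLAS
from .errors import ValidationError
from .flight import FlightProfile, make_flight_profile
from .io import (
    DIRECTIONS,
    EMG_RATE_HZ,
    GRAVITY_CONDITIONS,
    GRAVITY_LEVELS,
    MARKER_RATE_HZ,
    MUSCLES,
    TARGET_DISTANCES_CM,
    TouchEvent,
    TrialRecord,
)

__all__ = [
    "GeneratorParams",
    "ParticipantEffects",
    "FlightProfile",
    "make_flight_profile",
    "make_target_sequence",
    "beta_position_profile",
    "minimum_jerk_position",
    "simulate_movement",
    "simulate_emg",
    "emg_burst_envelope",
    "inject_defects",
    "simulate_experiment",
    "simulate_feature_table",
    "DEFECT_TYPES",
]

GRAVITY_SENSITIVE_MUSCLES = ("deltoid_anterior", "deltoid_posterior", "trapezius")


def _cond_table(normo: float, micro_up, micro_down, hyper_up, hyper_down) -> dict:
    return {
        ("normo", "up"): normo,
        ("normo", "down"): normo,
        ("micro", "up"): micro_up,
        ("micro", "down"): micro_down,
        ("hyper", "up"): hyper_up,
        ("hyper", "down"): hyper_down,
    }


@dataclass
class GeneratorParams:
    """All tunable knobs of the synthetic experiment.

    Durations are ``(base + per_cm * distance + participant shift) *
    multiplier(gravity, direction)``; endpoint bias and curvature are
    additive offsets per (gravity, direction).  ``lambda_attenuation``
    scales every gravity-effect delta when compensation is on.
    """

    # flight profile
    steady_s: float = 20.0
    pullup_s: float = 20.0
    weightless_s: float = 22.0
    rest_s: float = 5.0
    gravity_noise_sd: float = 0.01
    hyper_g: float = 1.8

    # movement timing (s)
    base_duration_s: float = 0.35
    duration_per_cm_s: float = 0.0125
    duration_multipliers: dict = field(
        default_factory=lambda: _cond_table(1.0, 1.30, 1.05, 0.90, 0.85)
    )
    duration_noise_sd_s: float = 0.05

    # endpoint bias (mm, + above target) and scatter
    endpoint_bias_mm: dict = field(
        default_factory=lambda: _cond_table(0.0, 0.5, 2.0, -6.0, -1.0)
    )
    endpoint_noise_sd_mm: float = 4.0
    touch_jitter_x_mm: float = 1.5

    # signed horizontal curvature amplitude (mm, + away from trunk)
    curvature_mm: dict = field(
        default_factory=lambda: _cond_table(-4.0, -9.0, -2.0, -4.5, -2.0)
    )
    curvature_noise_sd_mm: float = 1.5

    # velocity-profile asymmetry: relative time to peak velocity per direction
    rtpv: dict = field(default_factory=lambda: {"up": 0.44, "down": 0.47})
    rtpv_concentration: float = 5.0

    # compensation attenuation of gravity-effect deltas, in [0, 1]
    lambda_attenuation: float = 0.3

    # marker realism
    marker_noise_sd_mm: float = 0.3
    dropout_rate: float = 0.01
    dropout_max_run: int = 3
    n_reference_markers: int = 2
    reference_noise_sd_mm: float = 0.3

    # EMG: per-movement burst-envelope integral (mV s) at 1 g; sensitive
    # muscles scale with effective wrist gravity, pectoralis does not
    emg_burst_mv: dict = field(
        default_factory=lambda: {
            "deltoid_anterior": 0.60,
            "deltoid_posterior": 0.40,
            "trapezius": 0.50,
            "pectoralis": 0.30,
        }
    )
    emg_noise_floor_mv: float = 0.005
    emg_trial_cv: float = 0.15  # lognormal SD of per-trial, per-muscle gain

    # inter-participant random-effect SDs
    participant_duration_sd_s: float = 0.04
    participant_bias_sd_mm: float = 1.0
    participant_curvature_sd_mm: float = 1.0
    participant_emg_sd_rel: float = 0.10
    arm_support_mean_n: float = 18.6
    arm_support_sd_n: float = 4.8

    # recording window pad around each movement (s)
    margin_s: float = 0.5

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_attenuation <= 1.0:
            raise ValidationError("lambda_attenuation must lie in [0, 1]")
        for name in (
            "duration_noise_sd_s",
            "endpoint_noise_sd_mm",
            "curvature_noise_sd_mm",
            "marker_noise_sd_mm",
            "participant_duration_sd_s",
            "participant_bias_sd_mm",
            "participant_curvature_sd_mm",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    # -- condition-effect helpers ------------------------------------------
    def _effective(self, table: dict, gravity: str, direction: str, compensation: bool) -> float:
        base = table[("normo", direction)]
        delta = table[(gravity, direction)] - base
        if compensation:
            delta *= self.lambda_attenuation
        return base + delta

    def duration_s(self, gravity: str, direction: str, compensation: bool,
                   distance_cm: float, participant_shift_s: float = 0.0) -> float:
        mult = self._effective(self.duration_multipliers, gravity, direction, compensation)
        return (self.base_duration_s + self.duration_per_cm_s * distance_cm
                + participant_shift_s) * mult

    def bias_mm(self, gravity: str, direction: str, compensation: bool) -> float:
        return self._effective(self.endpoint_bias_mm, gravity, direction, compensation)

    def curvature_amp_mm(self, gravity: str, direction: str, compensation: bool) -> float:
        return self._effective(self.curvature_mm, gravity, direction, compensation)

    def effective_wrist_gravity(self, gravity: str, compensation: bool) -> float:
        return 1.0 if compensation else GRAVITY_LEVELS[gravity] if gravity != "hyper" else self.hyper_g


@dataclass(frozen=True)
class ParticipantEffects:
    """Per-participant random effects shared by all of that participant's trials."""

    duration_shift_s: float = 0.0
    bias_shift_mm: float = 0.0
    curvature_shift_mm: float = 0.0
    emg_gain: float = 1.0
    arm_support_force_n: float = 18.6


def draw_participant_effects(params: GeneratorParams, rng: np.random.Generator) -> ParticipantEffects:
    return ParticipantEffects(
        duration_shift_s=rng.normal(0.0, params.participant_duration_sd_s),
        bias_shift_mm=rng.normal(0.0, params.participant_bias_sd_mm),
        curvature_shift_mm=rng.normal(0.0, params.participant_curvature_sd_mm),
        emg_gain=float(np.exp(rng.normal(0.0, params.participant_emg_sd_rel))),
        arm_support_force_n=float(
            np.clip(rng.normal(params.arm_support_mean_n, params.arm_support_sd_n), 5.0, 40.0)
        ),
    )


# ---------------------------------------------------------------------------
# target sequences


def make_target_sequence(n_reps_per_target: int, seed: int) -> list[tuple[str, float]]:
    """Pseudo-random balanced target order.

    Each of the 14 (direction, distance) targets appears exactly
    ``n_reps_per_target`` times, with no more than 3 identical consecutive
    targets; deterministic given ``seed``.
    """
    if n_reps_per_target < 1:
        raise ValidationError("n_reps_per_target must be >= 1")
    targets = [(d, dist) for d in DIRECTIONS for dist in TARGET_DISTANCES_CM]
    seq = targets * n_reps_per_target
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(seq)))
    seq = [seq[i] for i in order]
    # break runs longer than 3 by swapping the offender with a later element
    for _ in range(100):
        run_at = _first_long_run(seq)
        if run_at is None:
            return seq
        swapped = False
        for j in range(run_at + 1, len(seq)):
            if seq[j] != seq[run_at]:
                seq[run_at], seq[j] = seq[j], seq[run_at]
                swapped = True
                break
        if not swapped:  # all remaining identical: swap backwards
            for j in range(run_at - 1, -1, -1):
                if seq[j] != seq[run_at]:
                    seq[run_at], seq[j] = seq[j], seq[run_at]
                    break
    return seq


def _first_long_run(seq: list) -> int | None:
    run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        if run > 3:
            return i
    return None


# ---------------------------------------------------------------------------
# trajectory primitives


def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement 10t^3 - 15t^4 + 6t^5 on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def beta_position_profile(tau: np.ndarray, rtpv: float, concentration: float = 5.0) -> np.ndarray:
    """Normalized displacement whose speed profile is a Beta density.

    The speed peaks at ``rtpv`` of the movement (Beta(a, b) mode with
    ``a = 1 + rtpv * c``, ``b = 1 + (1 - rtpv) * c``); ``rtpv = 0.5``
    gives a symmetric bell close to the minimum-jerk speed profile.
    """
    if not 0.0 < rtpv < 1.0:
        raise ValidationError("rtpv must lie in (0, 1)")
    a = 1.0 + rtpv * concentration
    b = 1.0 + (1.0 - rtpv) * concentration
    return sps.beta.cdf(np.clip(tau, 0.0, 1.0), a, b)


# ---------------------------------------------------------------------------
# single-trial simulation


def simulate_movement(
    gravity_condition: str,
    compensation: bool,
    direction: str,
    target_distance_cm: float,
    params: GeneratorParams,
    participant: ParticipantEffects | None = None,
    seed: int | np.random.SeedSequence = 0,
    participant_id: str = "S01",
    parabola_index: int = 1,
) -> tuple[TrialRecord, dict]:
    """Simulate one pointing movement; returns the trial and its ground truth.

    The marker path is a vertical beta-profile displacement to the touched
    endpoint plus a half-sine horizontal bulge of the configured signed
    amplitude, endpoint bias, and Gaussian marker noise; touch events are
    consistent with the trajectory and the press coordinate is the
    trajectory endpoint.
    """
    if gravity_condition not in GRAVITY_CONDITIONS:
        raise ValidationError(f"unknown gravity condition {gravity_condition!r}")
    if direction not in DIRECTIONS:
        raise ValidationError(f"unknown direction {direction!r}")
    if target_distance_cm not in TARGET_DISTANCES_CM:
        raise ValidationError(f"invalid target distance {target_distance_cm}")
    participant = participant or ParticipantEffects(
        arm_support_force_n=params.arm_support_mean_n
    )
    rng = np.random.default_rng(seed)
    sign = 1.0 if direction == "up" else -1.0

    T = params.duration_s(
        gravity_condition, direction, compensation, target_distance_cm,
        participant.duration_shift_s,
    )
    if params.duration_noise_sd_s > 0:
        T = max(0.15, T + rng.normal(0.0, params.duration_noise_sd_s))

    bias = params.bias_mm(gravity_condition, direction, compensation) + participant.bias_shift_mm
    if params.endpoint_noise_sd_mm > 0:
        bias = bias + rng.normal(0.0, params.endpoint_noise_sd_mm)
    curvature = (
        params.curvature_amp_mm(gravity_condition, direction, compensation)
        + participant.curvature_shift_mm
    )
    if params.curvature_noise_sd_mm > 0:
        curvature = curvature + rng.normal(0.0, params.curvature_noise_sd_mm)
    rtpv = params.rtpv[direction]

    margin = params.margin_s
    onset = margin
    offset = margin + T
    total_s = T + 2 * margin
    n_m = int(round(total_s * MARKER_RATE_HZ)) + 1
    t_m = np.arange(n_m) / MARKER_RATE_HZ
    tau = np.clip((t_m - onset) / T, 0.0, 1.0)

    target_y = sign * 10.0 * target_distance_cm
    end_y = target_y + bias
    end_x = rng.normal(0.0, params.touch_jitter_x_mm) if params.touch_jitter_x_mm > 0 else 0.0

    y = end_y * beta_position_profile(tau, rtpv, params.rtpv_concentration)
    x = end_x * tau + curvature * np.sin(np.pi * tau)
    z = np.zeros(n_m)
    xyz = np.column_stack([x, y, z])
    if params.marker_noise_sd_mm > 0:
        xyz = xyz + rng.normal(0.0, params.marker_noise_sd_mm, xyz.shape)

    # dropout runs (never the first or last sample)
    if params.dropout_rate > 0 and n_m > 4:
        k = 1
        while k < n_m - 1:
            if rng.random() < params.dropout_rate:
                run = int(rng.integers(1, params.dropout_max_run + 1))
                stop = min(k + run, n_m - 1)
                xyz[k:stop] = np.nan
                k = stop + 1
            k += 1

    ref = np.zeros((n_m, params.n_reference_markers, 3))
    ref_positions = np.array(
        [[-150.0 + 300.0 * j, -180.0, 0.0] for j in range(params.n_reference_markers)]
    )
    ref += ref_positions[None, :, :]
    if params.reference_noise_sd_mm > 0:
        ref = ref + rng.normal(0.0, params.reference_noise_sd_mm, ref.shape)

    start_jitter = rng.normal(0.0, 2.0, 2) if params.marker_noise_sd_mm > 0 else np.zeros(2)
    events = [
        TouchEvent(0.05, "press", float(start_jitter[0]), float(start_jitter[1])),
        TouchEvent(onset, "release", float(start_jitter[0]), float(start_jitter[1])),
        TouchEvent(offset, "press", float(end_x), float(end_y)),
    ]

    n_e = int(round(total_s * EMG_RATE_HZ)) + 1
    t_e = np.arange(n_e) / EMG_RATE_HZ
    g_nominal = params.hyper_g if gravity_condition == "hyper" else GRAVITY_LEVELS[gravity_condition]
    g_trace = np.full(n_e, g_nominal)
    if params.gravity_noise_sd > 0:
        g_trace = np.clip(g_trace + rng.normal(0.0, params.gravity_noise_sd, n_e), -0.2, 2.2)
    g_eff = 1.0 if compensation else g_nominal
    hand = np.full(n_e, g_eff)
    if params.gravity_noise_sd > 0:
        hand = np.clip(hand + rng.normal(0.0, params.gravity_noise_sd, n_e), -0.2, 2.2)

    trial = TrialRecord(
        participant_id=participant_id,
        parabola_index=parabola_index,
        gravity_condition=gravity_condition,
        compensation=compensation,
        direction=direction,
        target_distance_cm=target_distance_cm,
        t_markers=t_m,
        marker_xyz=xyz,
        reference_markers=ref,
        touch_events=events,
        t_emg=t_e,
        emg_raw=np.zeros((n_e, len(MUSCLES))),
        gravity_trace=g_trace,
        hand_gravity=hand,
    )
    trial.emg_raw = simulate_emg(trial, params, rng, g_eff=g_eff, emg_gain=participant.emg_gain)
    truth = {
        "participant_id": participant_id,
        "stem": trial.stem,
        "gravity_condition": gravity_condition,
        "compensation": compensation,
        "direction": direction,
        "target_distance_cm": target_distance_cm,
        "duration_s": T,
        "signed_deviation_mm": end_y - target_y,
        "curvature_mm": curvature,
        "rtpv": rtpv,
        "effective_gravity": g_eff,
        "defect": "",
    }
    return trial, truth


def emg_burst_envelope(
    t: np.ndarray, onset: float, offset: float, integral_mv_s: float,
    rtpv: float = 0.5, concentration: float = 5.0,
) -> np.ndarray:
    """Deterministic burst envelope (mV) spanning [onset, offset].

    Beta-density bell, zero outside the movement, scaled so its time
    integral equals ``integral_mv_s``: the configured gain is then the iEMG
    truth itself, independent of movement duration.
    """
    a = 1.0 + rtpv * concentration
    b = 1.0 + (1.0 - rtpv) * concentration
    T = max(offset - onset, 1e-9)
    tau = (t - onset) / T
    env = np.where((tau >= 0) & (tau <= 1), sps.beta.pdf(np.clip(tau, 0, 1), a, b), 0.0)
    return integral_mv_s * env / T


def simulate_emg(
    trial: TrialRecord,
    params: GeneratorParams,
    seed: int | np.random.Generator = 0,
    g_eff: float | None = None,
    emg_gain: float = 1.0,
) -> np.ndarray:
    """Four EMG channels: band-limited noise carrier modulated by a burst.

    Burst gain of the three gravity-sensitive shoulder muscles scales
    linearly with the effective gravity multiple at the wrist (1.0 under
    perfect compensation); the pectoralis gain is gravity-insensitive.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onset, offset = _movement_window(trial)
    if g_eff is None:
        g_eff = float(np.median(trial.hand_gravity))
    n = len(trial.t_emg)
    out = np.zeros((n, len(MUSCLES)))
    for i, muscle in enumerate(MUSCLES):
        amp = params.emg_burst_mv[muscle] * emg_gain
        if params.emg_trial_cv > 0:
            amp *= float(np.exp(rng.normal(0.0, params.emg_trial_cv)))
        gain = amp * g_eff if muscle in GRAVITY_SENSITIVE_MUSCLES else amp
        env = emg_burst_envelope(trial.t_emg, onset, offset, gain)
        carrier = _bandlimited_noise(n, rng)
        out[:, i] = env * carrier + params.emg_noise_floor_mv * rng.standard_normal(n)
    return out


def _bandlimited_noise(n: int, rng: np.random.Generator,
                       band: tuple[float, float] = (30.0, 300.0)) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to ``band`` Hz at the EMG rate."""
    from scipy.signal import butter, sosfiltfilt

    white = rng.standard_normal(n)
    if n < 30:
        return white
    sos = butter(2, band, btype="bandpass", fs=EMG_RATE_HZ, output="sos")
    shaped = sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / max(rms, 1e-12)


def _movement_window(trial: TrialRecord) -> tuple[float, float]:
    release = next(e.time_s for e in trial.touch_events if e.kind == "release")
    press = next(
        e.time_s for e in trial.touch_events if e.kind == "press" and e.time_s > release
    )
    return release, press


# ---------------------------------------------------------------------------
# defect injection

DEFECT_TYPES = (
    "gravity_change",
    "hand_gravity_change",
    "reference_drift",
    "missing_run",
    "marker_jump",
    "bad_start",
    "opposite_direction",
    "abnormal_trajectory",
)


def inject_defects(
    trials: list[TrialRecord],
    defect_spec: dict[str, int],
    seed: int = 0,
    qc_thresholds=None,
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Plant unambiguous QC defects into copies of ``trials``.

    ``defect_spec`` maps a defect type to the number of trials to corrupt;
    each corrupted trial gets exactly one defect, chosen without replacement.
    Defects are constructed strictly beyond the exclusion thresholds.
    Returns the (partly corrupted) trials and a ground-truth table with one
    row per planted defect (columns ``stem, defect``).
    """
    from .config import QCThresholds

    thr = qc_thresholds or QCThresholds()
    for kind in defect_spec:
        if kind not in DEFECT_TYPES:
            raise ValidationError(f"unknown defect type {kind!r}")
    total = sum(defect_spec.values())
    if total > len(trials):
        raise ValidationError("more defects requested than trials available")
    rng = np.random.default_rng(seed)
    victims = rng.choice(len(trials), size=total, replace=False)
    out = [t for t in trials]
    truth_rows = []
    k = 0
    for kind, count in defect_spec.items():
        for _ in range(count):
            idx = int(victims[k]); k += 1
            corrupted = _apply_defect(copy.deepcopy(trials[idx]), kind, rng, thr)
            out[idx] = corrupted
            truth_rows.append({"stem": corrupted.stem, "defect": kind})
    return out, pd.DataFrame(truth_rows, columns=["stem", "defect"])


def _apply_defect(trial: TrialRecord, kind: str, rng: np.random.Generator, thr) -> TrialRecord:
    onset, offset = _movement_window(trial)
    mid_e = (trial.t_emg >= (onset + offset) / 2)
    in_move_m = (trial.t_markers >= onset) & (trial.t_markers <= offset)
    move_idx = np.flatnonzero(in_move_m)
    sign = 1.0 if trial.direction == "up" else -1.0

    if kind == "gravity_change":
        g0 = float(np.median(trial.gravity_trace))
        g1 = 1.0 if abs(g0) < 0.5 or g0 > 1.4 else 0.0
        trial.gravity_trace = np.where(mid_e, g1, trial.gravity_trace)
        if not trial.compensation:
            trial.hand_gravity = trial.gravity_trace.copy()
    elif kind == "hand_gravity_change":
        h0 = float(np.median(trial.hand_gravity))
        h1 = 0.0 if h0 > 0.5 else 1.0
        trial.hand_gravity = np.where(mid_e, h1, trial.hand_gravity)
    elif kind == "reference_drift":
        n = len(trial.t_markers)
        walk = np.cumsum(rng.standard_normal(n))
        walk = (walk - walk.mean()) / max(walk.std(), 1e-9) * (2.0 * thr.reference_sd_mm)
        trial.reference_markers = trial.reference_markers.copy()
        trial.reference_markers[:, 0, 0] += walk
    elif kind == "missing_run":
        run = thr.max_missing_run + 1
        start = move_idx[len(move_idx) // 3]
        stop = min(start + run, len(trial.t_markers) - 1)
        trial.marker_xyz = trial.marker_xyz.copy()
        trial.marker_xyz[start:stop] = np.nan
    elif kind == "marker_jump":
        start = move_idx[len(move_idx) // 2]
        trial.marker_xyz = trial.marker_xyz.copy()
        trial.marker_xyz[start:, 0] += 1.6 * thr.jump_mm
    elif kind == "bad_start":
        r = 1.3 * thr.start_radius_mm
        trial.touch_events = [
            TouchEvent(e.time_s, e.kind, e.x_mm + r, e.y_mm) if e.kind == "release" else e
            for e in trial.touch_events
        ]
    elif kind == "opposite_direction":
        dip = 3.0 * thr.direction_deadband_mm
        tau = (trial.t_markers - onset) / max(offset - onset, 1e-9)
        bump = np.where((tau > 0) & (tau < 0.25), np.sin(np.pi * tau / 0.25), 0.0)
        trial.marker_xyz = trial.marker_xyz.copy()
        trial.marker_xyz[:, 1] -= sign * dip * bump
    elif kind == "abnormal_trajectory":
        tau = (trial.t_markers - onset) / max(offset - onset, 1e-9)
        zigzag = np.where((tau >= 0) & (tau <= 1), np.sin(2 * np.pi * 3 * tau), 0.0)
        trial.marker_xyz = trial.marker_xyz.copy()
        trial.marker_xyz[:, 0] += 50.0 * zigzag
    return trial


# ---------------------------------------------------------------------------
# whole experiments


def default_compensated_parabolas(n_parabolas: int) -> frozenset[int]:
    """Flight-protocol compensation schedule, scaled to shorter runs.

    Ten or more parabolas follow the flown protocol (compensation on 5-9);
    shorter simulated campaigns compensate the upper half so both levels of
    the factor are always observed.
    """
    if n_parabolas >= 10:
        return DEFAULT_COMPENSATED_PARABOLAS
    return frozenset(range(n_parabolas // 2 + 1, n_parabolas + 1))


def simulate_experiment(
    params: GeneratorParams | None = None,
    n_participants: int = 9,
    n_parabolas: int = 10,
    compensated_parabolas: frozenset[int] | set[int] | None = None,
    seed: int | None = None,
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Simulate a full balanced experiment.

    Each participant flies ``n_parabolas`` parabolas; in each measured phase
    (steady 1 g, pull-up, weightless) they point once at each of the 14
    targets in pseudo-random order.  Compensation follows the flight
    protocol (parabolas 5-9) unless overridden.  Returns the trials plus a
    per-trial ground-truth table.
    """
    params = params or GeneratorParams()
    if seed is None:
        seed = params.seed
    if compensated_parabolas is None:
        compensated_parabolas = default_compensated_parabolas(n_parabolas)
    root = np.random.SeedSequence(seed)
    part_ss, trial_ss = root.spawn(2)
    part_rng = np.random.default_rng(part_ss)
    trials: list[TrialRecord] = []
    truths: list[dict] = []
    counter = 0
    for p in range(n_participants):
        pid = f"S{p + 1:02d}"
        effects = draw_participant_effects(params, part_rng)
        for parab in range(1, n_parabolas + 1):
            comp = parab in compensated_parabolas
            for gravity in GRAVITY_CONDITIONS:
                gi = GRAVITY_CONDITIONS.index(gravity)
                seq_seed = (seed * 9973 + p * 331 + parab * 17 + gi) % (2**31)
                seq = make_target_sequence(1, seed=seq_seed)
                for direction, dist in seq:
                    trial, truth = simulate_movement(
                        gravity, comp, direction, dist, params,
                        participant=effects,
                        seed=np.random.SeedSequence(entropy=seed, spawn_key=(counter,)),
                        participant_id=pid,
                        parabola_index=parab,
                    )
                    counter += 1
                    trials.append(trial)
                    truths.append(truth)
    return trials, pd.DataFrame(truths)


def simulate_feature_table(
    params: GeneratorParams | None = None,
    n_participants: int = 9,
    n_reps_per_cell: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Movement-level kinematic features drawn directly from the generative model.

    Distribution-level shortcut that bypasses trajectory synthesis and
    feature extraction: durations, signed deviations, and curvatures are
    drawn from exactly the model :func:`simulate_movement` embeds (condition
    truth + participant random effect + trial noise).  Used for large
    simulation studies (power, type-I error, contrast patterns) where the
    extraction chain itself is validated elsewhere.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        pid = f"S{p + 1:02d}"
        eff = draw_participant_effects(params, rng)
        for gravity in GRAVITY_CONDITIONS:
            for comp in (False, True):
                for direction in DIRECTIONS:
                    for dist in TARGET_DISTANCES_CM:
                        for _ in range(n_reps_per_cell):
                            dur = params.duration_s(
                                gravity, direction, comp, dist, eff.duration_shift_s
                            )
                            dur = max(0.15, dur + rng.normal(0, params.duration_noise_sd_s))
                            dev = (
                                params.bias_mm(gravity, direction, comp)
                                + eff.bias_shift_mm
                                + rng.normal(0, params.endpoint_noise_sd_mm)
                            )
                            curv = (
                                params.curvature_amp_mm(gravity, direction, comp)
                                + eff.curvature_shift_mm
                                + rng.normal(0, params.curvature_noise_sd_mm)
                            )
                            rows.append(
                                (pid, direction, gravity, comp, dist, dur, dev, abs(dev), curv, True)
                            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "direction", "gravity_condition", "compensation",
            "target_distance_cm", "duration_s", "signed_deviation_mm",
            "absolute_deviation_mm", "curvature_mm", "retained",
        ],
    )
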