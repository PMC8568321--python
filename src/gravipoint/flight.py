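"""Parabolic-flight gravity profiles.

A parabola exposes the seated participant to three measured phases —
steady flight at ~1 g (20 s before parabola entry), the pull-up at ~1.8 g,
and the weightless phase at ~0 g — followed by a rest interval at 1 g.
Profiles are sampled at 1 kHz to match the accelerometer feeding the
compensation controller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

PHASES = ("steady_1g", "pullup_2g", "weightless_0g", "rest")
PHASE_GRAVITY = {"steady_1g": 1.0, "pullup_2g": 1.8, "weightless_0g": 0.0, "rest": 1.0}
#: measured phase per ambient condition label
CONDITION_PHASE = {"normo": "steady_1g", "hyper": "pullup_2g", "micro": "weightless_0g"}


@dataclass
class FlightProfile:
    """Gravity trace with phase and parabola labels, sampled at ``rate_hz``."""

    t: np.ndarray
    gravity: np.ndarray
    phase: np.ndarray       # one of PHASES per sample
    parabola: np.ndarray    # 1-based parabola index per sample
    rate_hz: float = 1000.0

    def phase_mask(self, parabola: int, phase: str) -> np.ndarray:
        return (self.parabola == parabola) & (self.phase == phase)


def make_flight_profile(
    n_parabolas: int,
    steady_s: float = 20.0,
    pullup_s: float = 20.0,
    weightless_s: float = 22.0,
    rest_s: float = 5.0,
    gravity_noise_sd: float = 0.0,
    hyper_g: float = 1.8,
    rate_hz: float = 1000.0,
    seed: int | None = None,
) -> FlightProfile:
    """Build an ``n_parabolas``-parabola profile of contiguous phases.

    Each parabola is steady -> pull-up -> weightless -> rest with nominal
    gravity {1.0, ``hyper_g``, 0.0, 1.0} g0 plus white measurement noise of
    SD ``gravity_noise_sd``.
    """
    if n_parabolas < 1:
        raise ValidationError("n_parabolas must be >= 1")
    rng = np.random.default_rng(seed)
    durations = {
        "steady_1g": steady_s,
        "pullup_2g": pullup_s,
        "weightless_0g": weightless_s,
        "rest": rest_s,
    }
    seg_phase: list[str] = []
    seg_parab: list[int] = []
    counts: list[int] = []
    for p in range(1, n_parabolas + 1):
        for ph in PHASES:
            n = int(round(durations[ph] * rate_hz))
            if n <= 0:
                continue
            seg_phase.append(ph)
            seg_parab.append(p)
            counts.append(n)
    total = int(np.sum(counts))
    t = np.arange(total) / rate_hz
    phase = np.repeat(np.array(seg_phase, dtype=object), counts).astype(str)
    parabola = np.repeat(np.array(seg_parab), counts)
    nominal = {**PHASE_GRAVITY, "pullup_2g": hyper_g}
    gravity = np.array([nominal[ph] for ph in seg_phase])
    gravity = np.repeat(gravity, counts)
    if gravity_noise_sd > 0:
        gravity = gravity + rng.normal(0.0, gravity_noise_sd, total)
    gravity = np.clip(gravity, -0.2, 2.2)
    return FlightProfile(t=t, gravity=gravity, phase=phase, parabola=parabola, rate_hz=rate_hz)
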