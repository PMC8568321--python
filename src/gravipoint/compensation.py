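"""Local gravity-compensation controller.

Two motors above and below the arm pull on thin strings strapped to the
wrist.  During compensation the net vertical force restores the 1 g
gravitational torque at the shoulder: with ``W`` the per-participant force
needed to hold the arm horizontal in 1 g and ``g`` the ambient gravity
multiple, the unclamped command is ``F = W * (1 - g)`` (positive downward —
weight is added in microgravity, removed in hypergravity).  The net force is
clamped to +/-30 N for safety.  Without compensation both motors hold a
constant 10 N pretension so the strings stay taut while applying zero net
force.  Strings only pull, so a small minimum holding tension keeps the
slack side taut while compensating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, GravipointError, ValidationError
from .flight import FlightProfile

FORCE_LIMIT_N = 30.0
PRETENSION_N = 10.0
DEFAULT_MIN_TENSION_N = 2.0
#: parabolas flown with compensation enabled under the flight protocol
DEFAULT_COMPENSATED_PARABOLAS = frozenset({5, 6, 7, 8, 9})


@dataclass(frozen=True)
class Calibration:
    """Force (N) required to hold the participant's arm horizontal in 1 g.

    Group calibration in flight was 18.6 +/- 4.8 N.
    """

    arm_support_force_n: float = 18.6

    def __post_init__(self) -> None:
        if not (self.arm_support_force_n > 0):
            raise ValidationError("arm_support_force_n must be strictly positive")


@dataclass(frozen=True)
class CompensationCommand:
    """Per-motor string tensions and net vertical force at one time step.

    ``net_force_n`` is positive downward and always equals
    ``lower_tension_n - upper_tension_n``.
    """

    net_force_n: float
    upper_tension_n: float
    lower_tension_n: float
    clamped: bool
    mode: str  # "compensating" | "pretension"

    def __post_init__(self) -> None:
        if self.upper_tension_n < 0 or self.lower_tension_n < 0:
            raise GravipointError("negative string tension requested")
        if not math.isclose(
            self.net_force_n, self.lower_tension_n - self.upper_tension_n,
            abs_tol=1e-9,
        ):
            raise GravipointError("net force inconsistent with tensions")


def required_force(
    gravity_multiple: float, calibration: Calibration
) -> tuple[float, bool]:
    """Net vertical force (N, positive downward) restoring 1 g shoulder torque.

    Returns ``(force, clamped)``; the force is ``W * (1 - g)`` clamped to
    [-30, +30] N with the flag set when the bound binds.
    """
    if not math.isfinite(gravity_multiple):
        raise ValidationError("gravity_multiple must be finite")
    raw = calibration.arm_support_force_n * (1.0 - gravity_multiple)
    clamped = abs(raw) > FORCE_LIMIT_N
    return (float(np.clip(raw, -FORCE_LIMIT_N, FORCE_LIMIT_N)), clamped)


def allocate_tensions(
    net_force_n: float,
    mode: str = "compensating",
    min_tension_n: float = DEFAULT_MIN_TENSION_N,
    clamped: bool = False,
) -> CompensationCommand:
    """Split a net vertical force into non-negative motor tensions.

    Compensating: the motor on the pulling side carries ``|net| +
    min_tension`` and the opposing motor ``min_tension``.  Pretension: both
    motors at 10 N, zero net force.
    """
    if mode == "pretension":
        return CompensationCommand(0.0, PRETENSION_N, PRETENSION_N, False, mode)
    if mode != "compensating":
        raise ValidationError(f"unknown mode {mode!r}")
    if abs(net_force_n) > FORCE_LIMIT_N + 1e-9:
        raise ValidationError(
            f"|net force| {abs(net_force_n):.3f} N exceeds the {FORCE_LIMIT_N} N clamp"
        )
    if min_tension_n < 0:
        raise GravipointError("min_tension_n must be non-negative")
    if net_force_n >= 0:  # pull downward: lower motor carries the load
        lower = net_force_n + min_tension_n
        upper = min_tension_n
    else:
        upper = -net_force_n + min_tension_n
        lower = min_tension_n
    return CompensationCommand(float(net_force_n), upper, lower, clamped, mode)


def closed_loop(
    profile: FlightProfile,
    calibration: Calibration,
    mode_schedule: dict[int, bool] | None = None,
    latency_samples: int = 1,
    smoothing_tau_s: float | None = None,
    min_tension_n: float = DEFAULT_MIN_TENSION_N,
) -> pd.DataFrame:
    """Run the 1 kHz controller over a flight profile.

    ``mode_schedule`` maps parabola index to compensation on/off; the default
    is the flight protocol (on for parabolas 5-9).  The command at sample k
    uses the gravity measurement at sample ``k - latency_samples``; an
    optional first-order exponential smoother (time constant
    ``smoothing_tau_s``) filters the gravity estimate.

    Returns a table with columns ``t, g, mode, net_N, upper_N, lower_N,
    clamped``.
    """
    if abs(profile.rate_hz - 1000.0) / 1000.0 > 0.01:
        raise FormatError(
            f"controller expects a 1000 Hz profile, got {profile.rate_hz} Hz"
        )
    if latency_samples < 0:
        raise ValidationError("latency_samples must be >= 0")
    g = np.asarray(profile.gravity, dtype=float)
    n = len(g)
    if latency_samples > 0:
        g_delayed = np.concatenate([np.full(latency_samples, g[0]), g[:-latency_samples]])
    else:
        g_delayed = g.copy()
    if smoothing_tau_s and smoothing_tau_s > 0:
        dt = 1.0 / profile.rate_hz
        alpha = dt / (smoothing_tau_s + dt)
        est = np.empty(n)
        acc = g_delayed[0]
        for k in range(n):
            acc += alpha * (g_delayed[k] - acc)
            est[k] = acc
        g_delayed = est

    if mode_schedule is None:
        mode_schedule = {
            int(p): int(p) in DEFAULT_COMPENSATED_PARABOLAS
            for p in np.unique(profile.parabola)
        }
    comp_on = np.array([mode_schedule.get(int(p), False) for p in profile.parabola])

    W = calibration.arm_support_force_n
    raw = W * (1.0 - g_delayed)
    net = np.clip(raw, -FORCE_LIMIT_N, FORCE_LIMIT_N)
    clamped = np.abs(raw) > FORCE_LIMIT_N

    net = np.where(comp_on, net, 0.0)
    clamped = np.where(comp_on, clamped, False)
    load = np.abs(net) + min_tension_n
    upper = np.where(comp_on, np.where(net < 0, load, min_tension_n), PRETENSION_N)
    lower = np.where(comp_on, np.where(net >= 0, load, min_tension_n), PRETENSION_N)
    mode = np.where(comp_on, "compensating", "pretension")
    return pd.DataFrame(
        {
            "t": profile.t,
            "g": g,
            "mode": mode,
            "net_N": net,
            "upper_N": upper,
            "lower_N": lower,
            "clamped": clamped,
        }
    )


def shoulder_torque_check(
    profile: FlightProfile,
    commands: pd.DataFrame,
    calibration: Calibration,
    lever_arm_m: float = 0.6,
) -> np.ndarray:
    """Residual shoulder torque (N m) relative to the 1 g baseline.

    The arm is modelled as loaded at the wrist with lever arm
    ``lever_arm_m``.  Residual = (W*g + F_net - W*1) * lever_arm; identically
    zero whenever compensation is active and the clamp does not bind.
    """
    if lever_arm_m <= 0:
        raise ValidationError("lever_arm_m must be positive")
    W = calibration.arm_support_force_n
    g = np.asarray(profile.gravity, dtype=float)
    net = commands["net_N"].to_numpy()
    return (W * g + net - W) * lever_arm_m
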