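"""Movement-level kinematic statistics.

Duration comes from the touchscreen (release to press), endpoint accuracy
from the touch press coordinate (signed vertical deviation, positive above
the target; overshoot = beyond the target in the movement direction),
curvature as the largest signed horizontal deviation of the marker path
from the onset-to-offset chord (positive away from the trunk), and movement
symmetry as the relative time to peak velocity (rTPV).  Movements with an
absolute deviation greater than 20 mm — the spacing between adjacent
targets — are excluded; exactly 20 mm is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SegmentationError, ValidationError
from .io import ScreenGeometry, TrialRecord
from .preprocess import SegmentedMovement

ACCURACY_LIMIT_MM = 20.0


@dataclass
class MovementFeatures:
    """Per-movement kinematics for one retained (or rejected) trial."""

    duration_s: float
    signed_deviation_mm: float
    absolute_deviation_mm: float
    overshoot: bool | None
    curvature_mm: float
    peak_speed_mm_s: float
    rtpv: float
    retained: bool = True


def movement_duration(segmented: SegmentedMovement) -> float:
    """Touchscreen movement time, offset - onset (s)."""
    d = segmented.offset_s - segmented.onset_s
    if d <= 0:
        raise SegmentationError("degenerate movement: offset <= onset")
    return float(d)


def endpoint_deviation(
    press_xy_mm: tuple[float, float],
    direction: str,
    target_distance_cm: float,
    geometry: ScreenGeometry | None = None,
) -> tuple[float, float, bool | None]:
    """Signed/absolute vertical deviation of the hit and overshoot flag.

    Positive signed deviation = hit above the target center.  Overshoot
    means beyond the target along the movement direction (above for upward
    movements, below for downward ones); at exactly zero the flag is None.
    """
    geometry = geometry or ScreenGeometry()
    _, ty = geometry.target_center(direction, target_distance_cm)
    signed = float(press_xy_mm[1] - ty)
    if signed == 0.0:
        overshoot: bool | None = None
    elif direction == "up":
        overshoot = signed > 0
    else:
        overshoot = signed < 0
    return signed, abs(signed), overshoot


def apply_accuracy_filter(
    features: pd.DataFrame, limit_mm: float = ACCURACY_LIMIT_MM
) -> pd.DataFrame:
    """Set ``retained`` = (absolute deviation <= limit) and (QC passed if present)."""
    out = features.copy()
    keep = out["absolute_deviation_mm"] <= limit_mm
    if "qc_passed" in out.columns:
        keep &= out["qc_passed"].astype(bool)
    out["retained"] = keep
    return out


def velocity_profile(trajectory: np.ndarray, t: np.ndarray) -> np.ndarray:
    """3-D speed (mm/s): norm of the central-difference position derivative."""
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.shape[0] < 3:
        raise ValidationError("velocity_profile needs at least 3 samples")
    if np.isnan(trajectory).any():
        raise ValidationError("velocity_profile requires a gap-free trajectory")
    vel = np.gradient(trajectory, t, axis=0)
    return np.linalg.norm(vel, axis=1)


def rtpv(speed: np.ndarray, t: np.ndarray, onset_s: float, offset_s: float) -> float:
    """Relative time to peak velocity: (argmax time - onset) / duration.

    Ties break to the earliest peak; a flat zero profile is undefined.
    """
    mask = (t >= onset_s) & (t <= offset_s)
    if not mask.any():
        raise ValidationError("speed series does not cover the movement window")
    s = np.asarray(speed)[mask]
    tt = np.asarray(t)[mask]
    if np.allclose(s, 0.0):
        raise ValidationError("rtpv undefined for a flat zero speed profile")
    peak_t = float(tt[int(np.argmax(s))])
    return (peak_t - onset_s) / (offset_s - onset_s)


def curvature_max_x(
    trajectory: np.ndarray,
    chord_relative: bool = True,
) -> float:
    """Signed horizontal deviation of largest magnitude (mm, + away from trunk).

    Each sample's x coordinate is measured relative to the straight chord
    from the first to the last sample (the raw-x-from-start alternative is
    available with ``chord_relative=False``).
    """
    trajectory = np.asarray(trajectory, dtype=float)
    start, end = trajectory[0], trajectory[-1]
    if np.linalg.norm(end - start) < 1e-9:
        raise ValidationError("degenerate chord: start equals end")
    if chord_relative:
        # interpolate chord x at each sample's fractional arc position along
        # the dominant (vertical) travel
        denom = end[1] - start[1]
        if abs(denom) < 1e-9:
            frac = np.linspace(0.0, 1.0, len(trajectory))
        else:
            frac = np.clip((trajectory[:, 1] - start[1]) / denom, 0.0, 1.0)
        chord_x = start[0] + frac * (end[0] - start[0])
        dev = trajectory[:, 0] - chord_x
    else:
        dev = trajectory[:, 0] - start[0]
    return float(dev[int(np.argmax(np.abs(dev)))])


def extract_features(
    trial: TrialRecord,
    segmented: SegmentedMovement,
    geometry: ScreenGeometry | None = None,
    qc_passed: bool = True,
    accuracy_limit_mm: float = ACCURACY_LIMIT_MM,
) -> MovementFeatures:
    """All kinematic features for one segmented movement."""
    geometry = geometry or ScreenGeometry()
    duration = movement_duration(segmented)
    signed, absolute, overshoot = endpoint_deviation(
        segmented.press_xy_mm, trial.direction, trial.target_distance_cm, geometry
    )
    mask = segmented.window_mask()
    traj = segmented.trajectory[mask]
    t = segmented.t[mask]
    speed = velocity_profile(traj, t)
    r = rtpv(speed, t, segmented.onset_s, segmented.offset_s)
    curv = curvature_max_x(traj)
    return MovementFeatures(
        duration_s=duration,
        signed_deviation_mm=signed,
        absolute_deviation_mm=absolute,
        overshoot=overshoot,
        curvature_mm=curv,
        peak_speed_mm_s=float(speed.max()),
        rtpv=r,
        retained=qc_passed and absolute <= accuracy_limit_mm,
    )


def features_table(
    trials: list[TrialRecord],
    qc: pd.DataFrame | None = None,
    geometry: ScreenGeometry | None = None,
    accuracy_limit_mm: float = ACCURACY_LIMIT_MM,
) -> pd.DataFrame:
    """Kinematic feature rows (with labels) for every segmentable trial.

    ``qc`` is the table from :func:`gravipoint.preprocess.qc_dataset`; trials
    that fail QC or cannot be segmented get ``retained = False``.
    """
    from .preprocess import segment_movement

    qc_map = {} if qc is None else dict(zip(qc["stem"], qc["passed"]))
    rows = []
    for trial in trials:
        base = {
            "stem": trial.stem,
            "participant_id": trial.participant_id,
            "parabola": trial.parabola_index,
            "gravity_condition": trial.gravity_condition,
            "compensation": trial.compensation,
            "direction": trial.direction,
            "target_distance_cm": trial.target_distance_cm,
        }
        passed = bool(qc_map.get(trial.stem, True))
        try:
            seg = segment_movement(trial, geometry)
            if np.isnan(seg.trajectory).any():
                raise ValidationError("unfilled gaps")
            f = extract_features(
                trial, seg, geometry, qc_passed=passed,
                accuracy_limit_mm=accuracy_limit_mm,
            )
        except (SegmentationError, ValidationError):
            rows.append({**base, "retained": False})
            continue
        rows.append(
            {
                **base,
                "duration_s": f.duration_s,
                "signed_deviation_mm": f.signed_deviation_mm,
                "absolute_deviation_mm": f.absolute_deviation_mm,
                "overshoot": f.overshoot,
                "curvature_mm": f.curvature_mm,
                "peak_speed_mm_s": f.peak_speed_mm_s,
                "rtpv": f.rtpv,
                "retained": f.retained,
            }
        )
    return pd.DataFrame(rows)
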