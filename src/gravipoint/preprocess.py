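"""Marker preprocessing and trial-level quality control.

Marker gaps are linearly interpolated (gap metadata kept for QC), the
trajectory is low-pass filtered with a zero-phase 2nd-order Butterworth
(10 Hz cut-off; the forward-backward pass doubles the effective magnitude
order), movements are segmented from touchscreen events (onset = stylus
release in the start circle, offset = next press), and eight exclusion
rules decide whether a trial enters the analysis:

1. the ambient gravity phase changes during the movement;
2. the hand-simulated (compensation) gravity level changes during it;
3. the SD of any stationary reference marker exceeds 4 mm;
4. more than five consecutive missing marker samples in the raw data;
5. a discontinuous jump between consecutive marker samples;
6. the movement does not start inside the start circle;
7. the stylus initially moves opposite to the target direction;
8. the trajectory is abnormal (path/chord ratio or speed cap).

Rules 5, 7 and 8 have no published thresholds; the defaults here
(50 mm/sample, 5 mm dead-band, ratio 2.0 / 5 m/s) are explicit conventions
recorded in the QC report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .config import QCThresholds
from .errors import SegmentationError, ValidationError
from .io import MARKER_RATE_HZ, ScreenGeometry, TrialRecord

QC_REASONS = (
    "gravity_change",
    "hand_gravity_change",
    "reference_drift",
    "missing_run",
    "marker_jump",
    "bad_start",
    "opposite_direction",
    "abnormal_trajectory",
    "inaccurate_endpoint",
)

#: nominal gravity levels used to classify ambient phases
_PHASE_LEVELS = np.array([0.0, 1.0, 1.8])


@dataclass
class GapMetadata:
    """Pre-interpolation description of missing-sample runs."""

    runs: list[tuple[int, int]] = field(default_factory=list)  # (start, length)
    leading_or_trailing: bool = False

    @property
    def max_run(self) -> int:
        return max((r[1] for r in self.runs), default=0)


@dataclass
class SegmentedMovement:
    """One movement delimited by touchscreen events, with processed markers."""

    onset_s: float
    offset_s: float
    t: np.ndarray
    trajectory: np.ndarray        # filtered, gap-free, full trial window
    press_xy_mm: tuple[float, float]
    gaps: GapMetadata

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise SegmentationError("offset must be after onset")

    def window_mask(self) -> np.ndarray:
        return (self.t >= self.onset_s) & (self.t <= self.offset_s)


@dataclass
class QCReport:
    """Machine-readable pass/fail verdict for one trial."""

    trial_stem: str
    passed: bool
    reasons: set[str]
    diagnostics: dict[str, float]
    default_thresholds_used: bool = True

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValidationError("passed flag inconsistent with reasons")


def interpolate_gaps(series: np.ndarray) -> tuple[np.ndarray, GapMetadata]:
    """Fill interior NaN runs by per-coordinate linear interpolation.

    Returns the filled series and gap metadata (run starts/lengths on the
    raw data).  Leading or trailing gaps are never extrapolated: they are
    recorded as exclusion-grade metadata and left to QC.
    """
    series = np.asarray(series, dtype=float)
    one_d = series.ndim == 1
    arr = series[:, None] if one_d else series.copy()
    missing = np.isnan(arr).any(axis=1)
    meta = GapMetadata(runs=_runs(missing))
    if missing[0] or missing[-1]:
        meta.leading_or_trailing = True
    idx = np.arange(len(arr))
    valid = ~missing
    if valid.sum() >= 2:
        out = arr.copy()
        for c in range(arr.shape[1]):
            out[missing, c] = np.interp(idx[missing], idx[valid], arr[valid, c])
        # do not fabricate data beyond the first/last valid sample
        first, last = idx[valid][0], idx[valid][-1]
        out[:first] = np.nan
        out[last + 1:] = np.nan
    else:
        out = arr
    return (out[:, 0] if one_d else out), meta


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(mask) - start))
    return runs


def lowpass_markers(
    series: np.ndarray,
    cutoff_hz: float = 10.0,
    order: int = 2,
    fs_hz: float = MARKER_RATE_HZ,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (order before the forward-backward pass).

    The two passes double the magnitude order and cancel phase, so the gain
    at the cut-off is 0.5 rather than 1/sqrt(2).  Endpoints are handled by
    scipy's odd reflective padding.
    """
    series = np.asarray(series, dtype=float)
    if np.isnan(series).any():
        raise ValidationError("lowpass_markers requires a gap-free series")
    padlen = 3 * (2 * order + 1)
    if series.shape[0] <= padlen:
        raise ValidationError(
            f"series of length {series.shape[0]} too short for padding {padlen}"
        )
    sos = butter(order, cutoff_hz, btype="lowpass", fs=fs_hz, output="sos")
    return sosfiltfilt(sos, series, axis=0, padlen=padlen)


def segment_movement(
    trial: TrialRecord,
    geometry: ScreenGeometry | None = None,
    cutoff_hz: float = 10.0,
) -> SegmentedMovement:
    """Segment one movement from touch events and attach processed markers.

    Onset is the release inside the start circle, offset the next press;
    duration is therefore a touchscreen quantity, invariant to any marker
    processing.  Raises :class:`SegmentationError` on malformed event
    streams (no release, consecutive same-kind events, press before
    release).
    """
    geometry = geometry or ScreenGeometry()
    kinds = [e.kind for e in trial.touch_events]
    if any(a == b for a, b in zip(kinds, kinds[1:])):
        raise SegmentationError(f"{trial.stem}: consecutive {kinds} events")
    releases = [e for e in trial.touch_events if e.kind == "release"]
    if not releases:
        raise SegmentationError(f"{trial.stem}: no release event")
    release = releases[0]
    presses = [
        e for e in trial.touch_events if e.kind == "press" and e.time_s > release.time_s
    ]
    if not presses:
        raise SegmentationError(f"{trial.stem}: no press after release")
    press = presses[0]

    filled, gaps = interpolate_gaps(trial.marker_xyz)
    if gaps.leading_or_trailing or np.isnan(filled).any():
        traj = filled  # leave NaNs; QC will reject via missing-run metadata
    else:
        traj = lowpass_markers(filled, cutoff_hz=cutoff_hz)
    return SegmentedMovement(
        onset_s=release.time_s,
        offset_s=press.time_s,
        t=trial.t_markers,
        trajectory=traj,
        press_xy_mm=(press.x_mm, press.y_mm),
        gaps=gaps,
    )


def qc_trial(
    trial: TrialRecord,
    segmented: SegmentedMovement | None = None,
    geometry: ScreenGeometry | None = None,
    thresholds: QCThresholds | None = None,
) -> QCReport:
    """Evaluate the eight exclusion rules; failures are report entries, not errors."""
    geometry = geometry or ScreenGeometry()
    thr = thresholds or QCThresholds()
    if segmented is None:
        segmented = segment_movement(trial, geometry)
    reasons: set[str] = set()
    diag: dict[str, float] = {}
    onset, offset = segmented.onset_s, segmented.offset_s
    sign = 1.0 if trial.direction == "up" else -1.0

    # 1 & 2: gravity phase stability during the movement
    for name, trace in (
        ("gravity_change", trial.gravity_trace),
        ("hand_gravity_change", trial.hand_gravity),
    ):
        in_move = (trial.t_emg >= onset) & (trial.t_emg <= offset)
        if in_move.any():
            levels = np.argmin(
                np.abs(np.asarray(trace)[in_move, None] - _PHASE_LEVELS[None, :]), axis=1
            )
            n_levels = len(np.unique(levels))
            diag[name] = float(n_levels)
            if n_levels > 1:
                reasons.add(name)

    # 3: stationary reference-marker stability
    if trial.reference_markers.size:
        sds = trial.reference_markers.std(axis=0)  # (n_markers, 3)
        worst = float(np.nanmax(sds))
        diag["reference_drift"] = worst
        if worst > thr.reference_sd_mm:
            reasons.add("reference_drift")

    # 4: missing-marker runs in the raw data
    max_run = segmented.gaps.max_run
    diag["missing_run"] = float(max_run)
    if max_run > thr.max_missing_run or segmented.gaps.leading_or_trailing:
        reasons.add("missing_run")

    # 5: discontinuous jumps between consecutive raw valid samples
    raw = trial.marker_xyz
    valid = ~np.isnan(raw).any(axis=1)
    if valid.sum() >= 2:
        pts = raw[valid]
        step = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        diag["marker_jump"] = float(step.max())
        if step.max() > thr.jump_mm:
            reasons.add("marker_jump")

    # 6: movement must start inside the start circle
    release = next(e for e in trial.touch_events if e.kind == "release")
    x0, y0 = geometry.start_position_mm
    start_dist = float(np.hypot(release.x_mm - x0, release.y_mm - y0))
    diag["bad_start"] = start_dist
    if start_dist > geometry.start_circle_diameter_mm / 2.0:
        reasons.add("bad_start")

    # rules 7 and 8 need a usable trajectory
    traj = segmented.trajectory
    if not np.isnan(traj).any():
        mask = segmented.window_mask()
        if mask.sum() >= 3:
            seg = traj[mask]
            # 7: initial motion opposite to the target direction
            y_rel = sign * (seg[:, 1] - seg[0, 1])
            fwd = np.flatnonzero(y_rel > thr.direction_deadband_mm)
            back = np.flatnonzero(y_rel < -thr.direction_deadband_mm)
            worst_back = float(-y_rel.min())
            diag["opposite_direction"] = worst_back
            if back.size and (not fwd.size or back[0] < fwd[0]):
                reasons.add("opposite_direction")

            # 8: abnormal trajectory (path/chord ratio or speed cap)
            path = float(np.linalg.norm(np.diff(seg, axis=0), axis=1).sum())
            chord = float(np.linalg.norm(seg[-1] - seg[0]))
            ratio = path / chord if chord > 1e-9 else np.inf
            speed = np.linalg.norm(np.gradient(seg, segmented.t[mask], axis=0), axis=1)
            diag["abnormal_trajectory"] = float(max(ratio, 0.0))
            diag["peak_speed_mm_s"] = float(speed.max())
            if ratio > thr.path_ratio_max or speed.max() > thr.speed_cap_mm_s:
                reasons.add("abnormal_trajectory")

    return QCReport(
        trial_stem=trial.stem,
        passed=not reasons,
        reasons=reasons,
        diagnostics=diag,
    )


def qc_dataset(
    trials: list[TrialRecord],
    geometry: ScreenGeometry | None = None,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Run QC on every trial; returns one row per trial (stem, passed, reasons)."""
    rows = []
    for trial in trials:
        try:
            report = qc_trial(trial, geometry=geometry, thresholds=thresholds)
            rows.append(
                {
                    "stem": trial.stem,
                    "passed": report.passed,
                    "reasons": ";".join(sorted(report.reasons)),
                }
            )
        except SegmentationError:
            rows.append({"stem": trial.stem, "passed": False, "reasons": "bad_start"})
    return pd.DataFrame(rows, columns=["stem", "passed", "reasons"])
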