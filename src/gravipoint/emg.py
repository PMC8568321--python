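"""EMG processing chain: band-pass, linear envelope, integrated EMG.

Raw channels (1,000 Hz) are band-pass filtered with a zero-phase 2nd-order
Butterworth (20-350 Hz), full-wave rectified and low-pass filtered at 6 Hz
(the classic linear envelope; the envelope algorithm itself is a convention
of this package), then integrated over the movement window to give iEMG in
mV s.  Normalization divides each participant x muscle by its own mean
normogravity-uncompensated iEMG, so 1.0 means "as in unassisted 1 g".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import FormatError, ValidationError
from .io import EMG_RATE_HZ, MUSCLES, TrialRecord


def bandpass_emg(
    raw: np.ndarray,
    band_hz: tuple[float, float] = (20.0, 350.0),
    fs_hz: float = EMG_RATE_HZ,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; rejects DC and drift."""
    lo, hi = band_hz
    if fs_hz < 2 * hi:
        raise FormatError(
            f"sampling rate {fs_hz} Hz below Nyquist for a {hi} Hz band edge"
        )
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValidationError("bandpass_emg requires finite input")
    sos = butter(order, (lo, hi), btype="bandpass", fs=fs_hz, output="sos")
    return sosfiltfilt(sos, raw, axis=0)


def envelope(
    filtered: np.ndarray,
    lowpass_hz: float = 6.0,
    fs_hz: float = EMG_RATE_HZ,
    order: int = 2,
) -> np.ndarray:
    """Linear envelope: full-wave rectification then zero-phase low-pass, clipped at 0."""
    rect = np.abs(np.asarray(filtered, dtype=float))
    sos = butter(order, lowpass_hz, btype="lowpass", fs=fs_hz, output="sos")
    return np.clip(sosfiltfilt(sos, rect, axis=0), 0.0, None)


def iemg(env: np.ndarray, t: np.ndarray, onset_s: float, offset_s: float) -> float:
    """Trapezoidal integral of the envelope over [onset, offset] (mV s)."""
    t = np.asarray(t)
    if onset_s < t[0] - 1e-9 or offset_s > t[-1] + 1e-9:
        raise ValidationError("movement window outside the recording")
    mask = (t >= onset_s) & (t <= offset_s)
    return float(np.trapezoid(np.asarray(env)[mask], t[mask]))


def emg_features_table(trials: list[TrialRecord],
                       band_hz: tuple[float, float] = (20.0, 350.0),
                       envelope_hz: float = 6.0) -> pd.DataFrame:
    """Per-movement, per-muscle iEMG rows (long format, labels attached).

    The 100 Hz-derived touchscreen onset/offset is applied directly to the
    1 kHz envelope (shared trial clock), without resampling.
    """
    from .preprocess import segment_movement

    rows = []
    for trial in trials:
        seg = segment_movement(trial)
        filt = bandpass_emg(trial.emg_raw, band_hz)
        env = envelope(filt, envelope_hz)
        for i, muscle in enumerate(MUSCLES):
            rows.append(
                {
                    "stem": trial.stem,
                    "participant_id": trial.participant_id,
                    "gravity_condition": trial.gravity_condition,
                    "compensation": trial.compensation,
                    "direction": trial.direction,
                    "target_distance_cm": trial.target_distance_cm,
                    "muscle": muscle,
                    "iemg_mv_s": iemg(env[:, i], trial.t_emg, seg.onset_s, seg.offset_s),
                }
            )
    return pd.DataFrame(rows)


def normalize_iemg(table: pd.DataFrame, value_col: str = "iemg_mv_s") -> pd.DataFrame:
    """Divide by each participant x muscle's mean normogravity-uncompensated iEMG.

    Raises :class:`ValidationError` when a participant x muscle has no
    normogravity-uncompensated movements or a zero reference mean.
    """
    ref = (
        table[
            (table["gravity_condition"] == "normo") & (~table["compensation"].astype(bool))
        ]
        .groupby(["participant_id", "muscle"])[value_col]
        .mean()
    )
    out = table.copy()
    norm = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        key = (row.participant_id, row.muscle)
        if key not in ref.index:
            raise ValidationError(
                f"no normogravity-uncompensated reference for {key}"
            )
        denom = ref.loc[key]
        if denom == 0:
            raise ValidationError(f"zero reference mean for {key}")
        norm[i] = getattr(row, value_col) / denom
    out["iemg_normalized"] = norm
    return out
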