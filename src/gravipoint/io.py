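"""Dataset schema, domain records, and delimited-text readers/writers.

One pointing movement is stored as four plain-text tables plus one row in a
dataset-level manifest:

``root/manifest.csv``
    columns ``participant_id, parabola, gravity_condition, compensation,
    direction, target_distance_cm, stem``
``root/<stem>_markers.csv``
    stylus marker and stationary reference markers at 100 Hz; missing stylus
    samples are empty cells, never zeros
``root/<stem>_emg.csv``
    four raw EMG channels at 1,000 Hz (mV)
``root/<stem>_events.csv``
    touchscreen press/release events with screen coordinates (mm)
``root/<stem>_gravity.csv``
    ambient and hand (wrist-effective) gravity traces at 1,000 Hz (g0)

Conventions fixed here for every downstream module: screen-frame x is
horizontal (positive away from the trunk), y vertical (positive up), z normal
to the screen; positions in millimetres, time in seconds from a shared clock
origin, gravity in multiples of g0, forces in newtons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

MARKER_RATE_HZ = 100.0
EMG_RATE_HZ = 1000.0
TARGET_DISTANCES_CM = (8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0)
MUSCLES = ("deltoid_anterior", "deltoid_posterior", "trapezius", "pectoralis")
GRAVITY_CONDITIONS = ("micro", "normo", "hyper")
#: nominal gravity multiple for each ambient condition
GRAVITY_LEVELS = {"micro": 0.0, "normo": 1.0, "hyper": 1.8}
DIRECTIONS = ("up", "down")

_MANIFEST_COLUMNS = [
    "participant_id",
    "parabola",
    "gravity_condition",
    "compensation",
    "direction",
    "target_distance_cm",
    "stem",
]


@dataclass(frozen=True)
class TouchEvent:
    """A single touchscreen press or release."""

    time_s: float
    kind: str  # "press" | "release"
    x_mm: float
    y_mm: float


@dataclass(frozen=True)
class ScreenGeometry:
    """Start/target layout on the touchscreen.

    The start circle is 60 mm in diameter, each target 20 mm; targets sit on
    the vertical axis through the start position at one of seven distances
    (80-200 mm) above or below it.
    """

    start_circle_diameter_mm: float = 60.0
    target_diameter_mm: float = 20.0
    start_position_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.start_circle_diameter_mm <= 0 or self.target_diameter_mm <= 0:
            raise ValidationError("circle diameters must be positive")

    def target_center(self, direction: str, distance_cm: float) -> tuple[float, float]:
        """Screen coordinate of a target's center (targets lie on the vertical axis)."""
        sign = 1.0 if direction == "up" else -1.0
        x0, y0 = self.start_position_mm
        return (x0, y0 + sign * 10.0 * distance_cm)


@dataclass
class TrialRecord:
    """One pointing movement's raw multimodal record.

    ``marker_xyz`` uses NaN for missing samples.  ``reference_markers`` has
    shape (n_samples, n_markers, 3).  ``hand_gravity`` is the effective
    gravity multiple at the wrist (equals ``gravity_trace`` without
    compensation, ~1 under compensation).
    """

    participant_id: str
    parabola_index: int
    gravity_condition: str
    compensation: bool
    direction: str
    target_distance_cm: float
    t_markers: np.ndarray
    marker_xyz: np.ndarray
    reference_markers: np.ndarray
    touch_events: list[TouchEvent]
    t_emg: np.ndarray
    emg_raw: np.ndarray
    gravity_trace: np.ndarray
    hand_gravity: np.ndarray

    @property
    def stem(self) -> str:
        return (
            f"{self.participant_id}_p{self.parabola_index:02d}"
            f"_{self.gravity_condition}_{'c1' if self.compensation else 'c0'}"
            f"_{self.direction}_{int(round(self.target_distance_cm)):02d}"
        )

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any domain-invariant breach."""
        if not 1 <= self.parabola_index:
            raise ValidationError(f"{self.stem}: parabola_index must be >= 1")
        if self.gravity_condition not in GRAVITY_CONDITIONS:
            raise ValidationError(
                f"{self.stem}: gravity_condition {self.gravity_condition!r}"
            )
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"{self.stem}: direction {self.direction!r}")
        if self.target_distance_cm not in TARGET_DISTANCES_CM:
            raise ValidationError(
                f"{self.stem}: target_distance_cm {self.target_distance_cm} "
                f"not one of {TARGET_DISTANCES_CM}"
            )
        if self.marker_xyz.shape != (len(self.t_markers), 3):
            raise ValidationError(f"{self.stem}: marker_xyz shape mismatch")
        if self.emg_raw.shape != (len(self.t_emg), len(MUSCLES)):
            raise ValidationError(f"{self.stem}: emg_raw shape mismatch")
        if len(self.gravity_trace) != len(self.t_emg):
            raise ValidationError(f"{self.stem}: gravity_trace length mismatch")
        g = np.asarray(self.gravity_trace)
        if g.size and (g.min() < -0.2 or g.max() > 2.2):
            raise ValidationError(
                f"{self.stem}: gravity_trace outside [-0.2, 2.2] g0"
            )
        _check_rate(self.t_markers, MARKER_RATE_HZ, self.stem + " markers")
        _check_rate(self.t_emg, EMG_RATE_HZ, self.stem + " emg")
        times = [e.time_s for e in self.touch_events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError(f"{self.stem}: touch_events out of time order")
        kinds = [e.kind for e in self.touch_events]
        if any(k not in ("press", "release") for k in kinds):
            raise ValidationError(f"{self.stem}: unknown touch event kind")
        if any(a == b for a, b in zip(kinds, kinds[1:])):
            raise ValidationError(f"{self.stem}: touch_events must alternate")


def _check_rate(t: np.ndarray, declared_hz: float, label: str) -> None:
    if len(t) < 2:
        return
    inferred = 1.0 / float(np.median(np.diff(t)))
    if abs(inferred - declared_hz) / declared_hz > 0.01:
        raise FormatError(
            f"{label}: declared {declared_hz} Hz but inferred {inferred:.2f} Hz"
        )


# ---------------------------------------------------------------------------
# writers / readers


def write_dataset(trials: Iterable[TrialRecord], root_path: str | Path) -> Path:
    """Write trials to ``root_path`` in the documented layout.

    Validates every trial first; an empty collection produces a valid dataset
    with an empty manifest.  Returns the dataset root.
    """
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        trial.validate()
        rows.append(
            {
                "participant_id": trial.participant_id,
                "parabola": trial.parabola_index,
                "gravity_condition": trial.gravity_condition,
                "compensation": int(trial.compensation),
                "direction": trial.direction,
                "target_distance_cm": trial.target_distance_cm,
                "stem": trial.stem,
            }
        )
        _write_trial_tables(trial, root)
    manifest = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    manifest.to_csv(root / "manifest.csv", index=False)
    return root


def _write_trial_tables(trial: TrialRecord, root: Path) -> None:
    n_ref = trial.reference_markers.shape[1] if trial.reference_markers.size else 0
    cols = {"t": trial.t_markers}
    for i, ax in enumerate("xyz"):
        cols[ax] = trial.marker_xyz[:, i]
    for j in range(n_ref):
        for i, ax in enumerate("xyz"):
            cols[f"ref{j + 1}_{ax}"] = trial.reference_markers[:, j, i]
    pd.DataFrame(cols).to_csv(
        root / f"{trial.stem}_markers.csv", index=False, float_format="%.17g"
    )

    emg = {"t": trial.t_emg}
    for i, name in enumerate(MUSCLES):
        emg[name] = trial.emg_raw[:, i]
    pd.DataFrame(emg).to_csv(
        root / f"{trial.stem}_emg.csv", index=False, float_format="%.17g"
    )

    ev = pd.DataFrame(
        [(e.time_s, e.kind, e.x_mm, e.y_mm) for e in trial.touch_events],
        columns=["t", "kind", "x", "y"],
    )
    ev.to_csv(root / f"{trial.stem}_events.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        {"t": trial.t_emg, "g_ambient": trial.gravity_trace, "g_hand": trial.hand_gravity}
    ).to_csv(root / f"{trial.stem}_gravity.csv", index=False, float_format="%.17g")


def read_dataset(root_path: str | Path) -> list[TrialRecord]:
    """Read every trial listed in ``root/manifest.csv``.

    Missing stylus-marker samples come back as NaN, preserving gap runs
    exactly.  Raises :class:`SchemaError` if the manifest or any referenced
    trial file is absent, :class:`FormatError` on sampling-rate mismatch.
    """
    root = Path(root_path)
    manifest_path = root / "manifest.csv"
    if not manifest_path.exists():
        raise SchemaError(f"missing manifest: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in _MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise SchemaError(f"{manifest_path}: missing columns {missing}")

    trials = []
    for row in manifest.itertuples(index=False):
        stem = row.stem
        paths = {
            kind: root / f"{stem}_{kind}.csv"
            for kind in ("markers", "emg", "events", "gravity")
        }
        for kind, p in paths.items():
            if not p.exists():
                raise SchemaError(f"manifest references nonexistent trial file: {p}")
        markers = pd.read_csv(paths["markers"])
        emg = pd.read_csv(paths["emg"])
        events = pd.read_csv(paths["events"])
        gravity = pd.read_csv(paths["gravity"])

        ref_stems = sorted(
            {c.rsplit("_", 1)[0] for c in markers.columns if c.startswith("ref")},
            key=lambda s: int(s[3:]),
        )
        n = len(markers)
        ref = np.empty((n, len(ref_stems), 3))
        for j, rs in enumerate(ref_stems):
            for i, ax in enumerate("xyz"):
                ref[:, j, i] = markers[f"{rs}_{ax}"].to_numpy()

        trial = TrialRecord(
            participant_id=str(row.participant_id),
            parabola_index=int(row.parabola),
            gravity_condition=str(row.gravity_condition),
            compensation=bool(row.compensation),
            direction=str(row.direction),
            target_distance_cm=float(row.target_distance_cm),
            t_markers=markers["t"].to_numpy(),
            marker_xyz=markers[["x", "y", "z"]].to_numpy(),
            reference_markers=ref,
            touch_events=[
                TouchEvent(float(e.t), str(e.kind), float(e.x), float(e.y))
                for e in events.itertuples(index=False)
            ],
            t_emg=emg["t"].to_numpy(),
            emg_raw=emg[list(MUSCLES)].to_numpy(),
            gravity_trace=gravity["g_ambient"].to_numpy(),
            hand_gravity=gravity["g_hand"].to_numpy(),
        )
        _check_rate(trial.t_markers, MARKER_RATE_HZ, f"{stem} markers")
        _check_rate(trial.t_emg, EMG_RATE_HZ, f"{stem} emg")
        trials.append(trial)
    return trials
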