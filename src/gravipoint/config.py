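"""Run configuration with YAML round-trip.

Defaults are the study's procedural constants: 10 Hz marker low-pass,
20-350 Hz EMG band-pass, 20 mm endpoint-accuracy cutoff, 4 mm stationary
reference-marker SD limit, 5-sample missing-run limit, 30 N force clamp,
10 N pretension, Bonferroni family of 6 planned comparisons.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class QCThresholds:
    """Trial-exclusion thresholds; the unpublished ones are explicit conventions."""

    reference_sd_mm: float = 4.0          # stationary marker SD limit
    max_missing_run: int = 5              # > this many consecutive gaps fails
    jump_mm: float = 50.0                 # inter-sample displacement limit
    start_radius_mm: float = 30.0         # start-circle radius (60 mm diameter)
    direction_deadband_mm: float = 5.0    # opposite-start dead-band
    path_ratio_max: float = 2.0           # path length / chord length limit
    speed_cap_mm_s: float = 5000.0        # physiological speed cap
    gravity_tolerance: float = 0.25       # half-width for phase classification


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate -> qc -> features -> stats)."""

    seed: int = 0
    marker_lowpass_hz: float = 10.0
    marker_filter_order: int = 2
    emg_band_hz: tuple[float, float] = (20.0, 350.0)
    emg_envelope_hz: float = 6.0
    accuracy_limit_mm: float = 20.0
    bonferroni_family: int = 6
    qc: QCThresholds = field(default_factory=QCThresholds)
    generator_overrides: dict = field(default_factory=dict)
    n_participants: int = 9
    n_parabolas: int = 10
    out_dir: str = "results"
    make_plots: bool = True

    def __post_init__(self) -> None:
        self.emg_band_hz = tuple(self.emg_band_hz)  # type: ignore[assignment]
        if isinstance(self.qc, dict):
            self.qc = QCThresholds(**self.qc)
        if self.accuracy_limit_mm <= 0 or self.marker_lowpass_hz <= 0:
            raise ValidationError("thresholds must be positive")
        if self.bonferroni_family < 1:
            raise ValidationError("bonferroni_family must be >= 1")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        data["emg_band_hz"] = list(self.emg_band_hz)
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
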