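"""Core domain dataclasses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

BP_CLASSES = ("normotensive", "prehypertensive", "hypertensive")


@dataclass(frozen=True)
class PulseParams:
    """Parameters of the 3-component (systolic + reflected + dicrotic) beat model.

    All times are in seconds from beat onset; amplitudes in arbitrary units.
    """

    t_sys: float
    t_refl: float
    t_dicrotic: float
    amp_sys: float
    amp_refl: float
    amp_dicrotic: float
    width_sys: float
    width_refl: float
    width_dicrotic: float
    noise_sd: float = 0.01
    baseline_drift_amp: float = 0.04
    drift_freq_hz: float = 0.25
    drift_phase: float = 0.0

    def validate(self) -> None:
        if not (self.t_sys < self.t_refl < self.t_dicrotic):
            raise ValueError("component centers must satisfy t_sys < t_refl < t_dicrotic")
        if not (self.amp_sys > self.amp_refl > 0):
            raise ValueError("need amp_sys > amp_refl > 0")
        if not (self.amp_sys > self.amp_dicrotic > 0):
            raise ValueError("need amp_sys > amp_dicrotic > 0")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    bp_class: str
    sbp: float
    dbp: float
    heart_rate: float
    pulse_params: PulseParams
    age: int = 50
    sex: str = "F"
    height_cm: float = 165.0
    weight_kg: float = 65.0

    @property
    def beat_period(self) -> float:
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class RawRecord:
    """One short single-channel PPG sample sequence."""

    subject_id: str
    record_index: int
    samples: np.ndarray
    fs: float = 1000.0

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class WaveformSet:
    """Filtered PPG plus first (vpg), second (apg) and third derivative, shared time base."""

    ppg: np.ndarray
    vpg: np.ndarray
    apg: np.ndarray
    jerk: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        n = len(self.ppg)
        if not (len(self.vpg) == len(self.apg) == len(self.jerk) == n):
            raise ValueError("all waveforms must share one length")

    def level(self, k: int) -> np.ndarray:
        """Waveform at derivative level k (0=PPG, 1=VPG, 2=APG, 3=third)."""
        try:
            return (self.ppg, self.vpg, self.apg, self.jerk)[k]
        except IndexError:
            raise ValueError(f"derivative level out of range: {k}") from None


@dataclass(frozen=True)
class QualityReport:
    skewness: tuple
    selected_index: int


@dataclass
class BeatFiducials:
    """Per-beat landmark sample indices; ``None`` marks a missing landmark.

    ``beat_start``/``beat_end`` delimit the half-open beat interval; ``beat_end``
    is also the next beat's onset.
    """

    beat_start: int
    beat_end: int
    t_O: Optional[int] = None
    t_S: Optional[int] = None
    t_N: Optional[int] = None
    t_D: Optional[int] = None
    t_w: Optional[int] = None
    t_x: Optional[int] = None
    t_y: Optional[int] = None
    t_z: Optional[int] = None
    t_a: Optional[int] = None
    t_b: Optional[int] = None
    t_c: Optional[int] = None
    t_d: Optional[int] = None
    t_e: Optional[int] = None

    def time_of(self, base: str) -> Optional[int]:
        if base == "Onext":
            return self.beat_end
        return getattr(self, f"t_{base}")


@dataclass
class RankingResult:
    method: str
    ordered_features: list = field(default_factory=list)
    scores: list = field(default_factory=list)

    def top_k(self, k: int = 10) -> list:
        if k < 0:
            raise ValueError("k must be >= 0")
        return list(self.ordered_features[:k])
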