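"""Record quality scoring, bandpass filtering and derivative construction.

The quality index is the plain moment skewness of the raw record; the best of
a subject's short records is kept.  The selected record is bandpass filtered
with a zero-phase fourth-order Chebyshev type-II design (stopband edges
0.5–10 Hz) and differentiated up to third order with central differences.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError
from .types import QualityReport, RawRecord, WaveformSet

DEFAULT_BAND = (0.5, 10.0)
DEFAULT_ORDER = 4
# 40 dB (80 dB after forward-backward application) keeps the second and third
# derivatives usable at 1 kHz; 20 dB leaves them noise-dominated.
DEFAULT_STOPBAND_DB = 40.0


def skewness_sqi(samples: Sequence[float]) -> float:
    """Moment-based sample skewness m3 / m2^(3/2) (no bias correction).

    Raises :class:`DegenerateSignalError` for constant or too-short input,
    where the ratio is undefined.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise DegenerateSignalError("skewness needs at least 3 samples")
    x = x - x.mean()
    m2 = np.mean(x**2)
    if m2 == 0.0:
        raise DegenerateSignalError("skewness undefined for a constant signal")
    m3 = np.mean(x**3)
    return float(m3 / m2**1.5)


def select_best_record(records: Sequence[RawRecord]) -> QualityReport:
    """Score each record by skewness and pick the argmax (ties: lowest index).

    Constant records score ``-inf`` so any informative record beats them.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    scores = []
    for rec in records:
        try:
            scores.append(skewness_sqi(rec.samples))
        except DegenerateSignalError:
            scores.append(float("-inf"))
    best = int(np.argmax(scores))  # argmax returns the first maximum
    return QualityReport(skewness=tuple(scores), selected_index=best)


def design_bandpass(fs: float, band=DEFAULT_BAND, order: int = DEFAULT_ORDER,
                    stopband_db: float = DEFAULT_STOPBAND_DB) -> np.ndarray:
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band edges: {band}")
    if fs <= 2 * hi:
        raise ValueError(f"fs={fs} too low for the {hi} Hz band edge")
    return sps.cheby2(order, stopband_db, [lo, hi], btype="bandpass", fs=fs,
                      output="sos")


def bandpass_filter(samples: Sequence[float], fs: float, band=DEFAULT_BAND,
                    order: int = DEFAULT_ORDER,
                    stopband_db: float = DEFAULT_STOPBAND_DB) -> np.ndarray:
    """Zero-phase (forward-backward) Chebyshev-II bandpass; length preserved."""
    sos = design_bandpass(fs, band, order, stopband_db)
    x = np.asarray(samples, dtype=float)
    return sps.sosfiltfilt(sos, x)


def differentiate(samples: Sequence[float], fs: float, order: int = 1,
                  smooth: bool = False) -> np.ndarray:
    """Central-difference derivative applied ``order`` times, scaled by fs.

    Boundary samples use one-sided differences (``np.gradient`` convention).
    Optional 5-point moving-average smoothing after each differentiation.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    x = np.asarray(samples, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 samples to differentiate")
    for _ in range(order):
        x = np.gradient(x) * fs
        if smooth:
            x = np.convolve(x, np.ones(5) / 5.0, mode="same")
    return x


def build_waveform_set(samples: Sequence[float], fs: float, *,
                       filtered: bool = True, band=DEFAULT_BAND,
                       order: int = DEFAULT_ORDER,
                       stopband_db: float = DEFAULT_STOPBAND_DB) -> WaveformSet:
    """Filter (optionally) and differentiate a record into a WaveformSet."""
    x = np.asarray(samples, dtype=float)
    if filtered:
        x = bandpass_filter(x, fs, band, order, stopband_db)
    vpg = differentiate(x, fs, 1)
    apg = differentiate(vpg, fs, 1)
    jerk = differentiate(apg, fs, 1)
    return WaveformSet(ppg=x, vpg=vpg, apg=apg, jerk=jerk, fs=fs)


def preprocess_subject(records: Sequence[RawRecord], **kwargs) -> tuple[QualityReport, WaveformSet]:
    """Select the best record of a subject and build its WaveformSet."""
    report = select_best_record(records)
    rec = records[report.selected_index]
    return report, build_waveform_set(rec.samples, rec.fs, **kwargs)
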