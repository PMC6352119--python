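"""Feature-kernel evaluation, per-subject aggregation and z-scoring.

Conventions
-----------
- Baseline: PPG-level values are corrected by the beat-onset PPG value;
  derivative levels (VPG/APG/third) use baseline 0.
- Time spans are in ms; areas are trapezoidal integrals divided by fs;
  power areas are raw square sums over the closed sample interval.
- A missing landmark yields NaN for every feature that touches it.
- Per-subject aggregation over beats is the NaN-excluding median.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import catalogue as cat
from ._tokens import parse_token
from .types import BeatFiducials, WaveformSet

log = logging.getLogger(__name__)

META_COLUMNS = ["subject_id", "sbp", "dbp", "bp_class"]


# ---------------------------------------------------------------------------
# kernel primitives (one beat)

def _t(fids: BeatFiducials, tok_text: str) -> Optional[int]:
    return fids.time_of(parse_token(tok_text).base)


def _baseline(wave: WaveformSet, fids: BeatFiducials, level: int) -> float:
    return float(wave.ppg[fids.time_of("O")]) if level == 0 else 0.0


def _value_at(wave: WaveformSet, fids: BeatFiducials, tok_text: str,
              level: Optional[int] = None) -> float:
    tok = parse_token(tok_text)
    lvl = tok.level if level is None else level
    t = fids.time_of(tok.base)
    if t is None:
        return float("nan")
    return float(wave.level(lvl)[t]) - _baseline(wave, fids, lvl)


def time_span(f1: str, f2: str, fids: BeatFiducials, fs: float) -> float:
    """(t2 - t1) in milliseconds."""
    t1, t2 = _t(fids, f1), _t(fids, f2)
    if t1 is None or t2 is None:
        return float("nan")
    return (t2 - t1) / fs * 1000.0


def amplitude(token: str, wave: WaveformSet, fids: BeatFiducials) -> float:
    """PPG-level height above the beat-onset baseline."""
    tok = parse_token(token)
    if tok.level != 0:
        raise ValueError(f"amplitude token must project to PPG level: {token}")
    return _value_at(wave, fids, token)


def value(token: str, wave: WaveformSet, fids: BeatFiducials) -> float:
    """Waveform value at the token's own derivative level (baseline 0)."""
    return _value_at(wave, fids, token)


def _interval(f1: str, f2: str, fids: BeatFiducials) -> tuple[Optional[int], Optional[int], int]:
    tok1, tok2 = parse_token(f1), parse_token(f2)
    if tok1.level != tok2.level:
        raise ValueError(f"interval endpoints on different levels: {f1}, {f2}")
    return _t(fids, f1), _t(fids, f2), tok1.level


def curve_area(f1: str, f2: str, wave: WaveformSet, fids: BeatFiducials,
               fs: float) -> float:
    """Trapezoidal integral of the baseline-corrected PPG between landmarks."""
    t1, t2, level = _interval(f1, f2, fids)
    if t1 is None or t2 is None or t1 > t2:
        return float("nan")
    if t1 == t2:
        return 0.0
    seg = wave.level(level)[t1:t2 + 1] - _baseline(wave, fids, level)
    return float(np.trapezoid(seg) / fs)


def power_area(f1: str, f2: str, wave: WaveformSet, fids: BeatFiducials) -> float:
    """Sum of squared baseline-corrected samples over the closed interval."""
    t1, t2, level = _interval(f1, f2, fids)
    if t1 is None or t2 is None or t1 > t2:
        return float("nan")
    seg = wave.level(level)[t1:t2 + 1] - _baseline(wave, fids, level)
    return float(np.sum(seg**2))


def slope(f1: str, f2: str, wave: WaveformSet, fids: BeatFiducials,
          fs: float) -> float:
    """Chord slope between two landmark values on their (shared) level."""
    t1, t2, level = _interval(f1, f2, fids)
    if t1 is None or t2 is None or t1 == t2:
        return float("nan")
    v1 = _value_at(wave, fids, f1, level)
    v2 = _value_at(wave, fids, f2, level)
    return (v2 - v1) / ((t2 - t1) / fs)


def ratio(num: float, den: float) -> float:
    if np.isnan(num) or np.isnan(den) or den == 0.0:
        return float("nan")
    return num / den


def apg_combo(terms: Sequence[str], wave: WaveformSet, fids: BeatFiducials) -> float:
    """Signed APG combination: first term minus the remaining terms."""
    vals = [_value_at(wave, fids, t) for t in terms]
    if any(np.isnan(v) for v in vals):
        return float("nan")
    return vals[0] - sum(vals[1:])


# ---------------------------------------------------------------------------
# catalogue evaluation

def _eval_spec(kernel: str, operands: dict, wave: WaveformSet,
               fids: BeatFiducials) -> float:
    fs = wave.fs
    if kernel == "span":
        return time_span(operands["f1"], operands["f2"], fids, fs)
    if kernel == "amp":
        return amplitude(operands["token"], wave, fids)
    if kernel == "val":
        return value(operands["token"], wave, fids)
    if kernel == "area":
        return curve_area(operands["f1"], operands["f2"], wave, fids, fs)
    if kernel == "pow":
        return power_area(operands["f1"], operands["f2"], wave, fids)
    if kernel == "slope":
        return slope(operands["f1"], operands["f2"], wave, fids, fs)
    if kernel == "apg_combo":
        return apg_combo(operands["terms"], wave, fids)
    if kernel == "ratio":
        num = _eval_spec(operands["num"]["kernel"], operands["num"]["operands"], wave, fids)
        den = _eval_spec(operands["den"]["kernel"], operands["den"]["operands"], wave, fids)
        return ratio(num, den)
    raise ValueError(f"unknown kernel: {kernel}")


def evaluate_beat(wave: WaveformSet, fids: BeatFiducials,
                  entries=None) -> dict[str, float]:
    """Evaluate the full catalogue on one beat."""
    entries = cat.catalogue() if entries is None else entries
    return {e.name: _eval_spec(e.kernel, e.operands, wave, fids) for e in entries}


def extract_features(wave: WaveformSet, beats: Sequence[BeatFiducials],
                     entries=None) -> dict[str, float]:
    """Median-aggregate the per-beat catalogue values across beats."""
    entries = cat.catalogue() if entries is None else entries
    names = [e.name for e in entries]
    if len(beats) == 0:
        log.warning("no complete beats: returning an all-missing feature vector")
        return {n: float("nan") for n in names}
    per_beat = [evaluate_beat(wave, bf, entries) for bf in beats]
    out = {}
    for n in names:
        vals = np.array([pb[n] for pb in per_beat], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN median
            out[n] = float(np.nanmedian(vals))
    return out


# ---------------------------------------------------------------------------
# cohort table

def build_feature_table(subject_features: dict[str, dict[str, float]],
                        meta: pd.DataFrame) -> pd.DataFrame:
    """Assemble the subjects × features table with metadata columns first.

    ``meta`` must have subject_id, sbp, dbp columns; bp_class is derived.
    """
    from .stratify import assign_bp_class

    names = cat.feature_names()
    rows = []
    for _, m in meta.iterrows():
        sid = str(m["subject_id"])
        feats = subject_features.get(sid, {n: float("nan") for n in names})
        row = {"subject_id": sid, "sbp": float(m["sbp"]), "dbp": float(m["dbp"]),
               "bp_class": assign_bp_class(float(m["sbp"]), float(m["dbp"]))}
        row.update({n: feats.get(n, float("nan")) for n in names})
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + names)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def fit_normalizer(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-feature mean and population SD over non-missing entries."""
    if len(table) < 2:
        raise ValueError("need at least 2 subjects to normalize")
    cols = feature_columns(table)
    X = table[cols]
    mean = X.mean(skipna=True)
    sd = X.std(skipna=True, ddof=0)
    return mean, sd


def apply_normalizer(table: pd.DataFrame, mean: pd.Series, sd: pd.Series) -> pd.DataFrame:
    """Z-score feature columns; zero-variance columns become all-zero."""
    out = table.copy()
    cols = feature_columns(table)
    for c in cols:
        if sd[c] == 0 or np.isnan(sd[c]):
            if sd[c] == 0:
                log.warning("zero-variance feature left as zeros: %s", c)
            out[c] = 0.0 * out[c]  # keeps NaN as NaN
        else:
            out[c] = (out[c] - mean[c]) / sd[c]
    return out


def normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level z-scoring (population-SD convention)."""
    mean, sd = fit_normalizer(table)
    return apply_normalizer(table, mean, sd)
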