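"""Synthetic PPG cohort generator.

Each beat is the sum of three positive Gaussian bumps (systolic, reflected,
dicrotic).  The blood-pressure class acts on the reflected wave: its delay
after the systolic component shrinks and its relative amplitude grows from
normotensive through hypertensive, so reflection-sensitive morphological
features carry the class signal.  Records are 2.1 s at 1 kHz by default and
quantised to a 12-bit integer grid, three records per subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import BP_CLASSES, PulseParams, RawRecord, SubjectProfile
from .stratify import assign_bp_class

ADC_BITS = 12
ADC_LEVELS = 2**ADC_BITS  # 4096

# Class-conditioned beat-shape parameters, as fractions of the beat period.
# refl_gap: delay of the reflected component after the systolic one (shrinks
# with BP); refl_ratio: reflected/systolic amplitude (grows with BP).
_CLASS_SHAPE = {
    "normotensive": {"refl_gap": 0.280, "refl_ratio": 0.34},
    "prehypertensive": {"refl_gap": 0.215, "refl_ratio": 0.46},
    "hypertensive": {"refl_gap": 0.150, "refl_ratio": 0.60},
}
_SHAPE_SD = {"refl_gap": 0.034, "refl_ratio": 0.085}


def _sample_bp(bp_class: str, rng: np.random.Generator) -> tuple[float, float]:
    """Draw (SBP, DBP) inside the class range, rounded to 0.1 mmHg.

    Rejection loop guards the class round-trip against rounding across a
    boundary (e.g. 119.96 -> 120.0).
    """
    for _ in range(100):
        if bp_class == "normotensive":
            sbp, dbp = rng.uniform(90, 120), rng.uniform(60, 80)
        elif bp_class == "prehypertensive":
            if rng.random() < 0.5:
                sbp, dbp = rng.uniform(120, 140), rng.uniform(60, 90)
            else:
                sbp, dbp = rng.uniform(90, 140), rng.uniform(80, 90)
        elif bp_class == "hypertensive":
            # ceilings 180/110: plausible stage-2 upper bounds
            if rng.random() < 0.5:
                sbp, dbp = rng.uniform(140, 180), rng.uniform(60, 110)
            else:
                sbp, dbp = rng.uniform(90, 180), rng.uniform(90, 110)
        else:
            raise ValueError(
                f"unknown BP class: {bp_class!r}; expected one of {BP_CLASSES}")
        sbp, dbp = round(sbp, 1), round(dbp, 1)
        if assign_bp_class(sbp, dbp) == bp_class:
            return sbp, dbp
    raise RuntimeError("BP rejection sampling failed")  # pragma: no cover


def sample_subject(bp_class: str, rng: np.random.Generator, *,
                   subject_id: str = "s0", effect_scale: float = 1.0) -> SubjectProfile:
    """Draw a subject profile with class-consistent BP and beat-shape params.

    ``effect_scale`` interpolates the class effect on beat morphology between
    none (0.0: every class shares the normotensive shape distribution) and the
    default (1.0).
    """
    if bp_class not in BP_CLASSES:
        raise ValueError(f"unknown BP class: {bp_class!r}; expected one of {BP_CLASSES}")
    sbp, dbp = _sample_bp(bp_class, rng)

    # lower clip keeps >= 2 complete beats inside a 2.1 s record
    hr = float(np.clip(rng.normal(76, 5), 68, 92))
    period = 60.0 / hr

    base = _CLASS_SHAPE["normotensive"]
    tgt = _CLASS_SHAPE[bp_class]
    gap_mean = base["refl_gap"] + effect_scale * (tgt["refl_gap"] - base["refl_gap"])
    ratio_mean = base["refl_ratio"] + effect_scale * (tgt["refl_ratio"] - base["refl_ratio"])
    refl_gap = float(np.clip(rng.normal(gap_mean, _SHAPE_SD["refl_gap"]), 0.08, 0.40))
    refl_ratio = float(np.clip(rng.normal(ratio_mean, _SHAPE_SD["refl_ratio"]), 0.05, 0.90))

    t_sys = float(np.clip(rng.normal(0.20, 0.012), 0.15, 0.25)) * period
    t_refl = t_sys + refl_gap * period
    t_dic = t_refl + float(np.clip(rng.normal(0.22, 0.015), 0.16, 0.28)) * period
    amp_sys = float(np.clip(rng.normal(1.0, 0.08), 0.5, 1.5))
    params = PulseParams(
        t_sys=t_sys,
        t_refl=t_refl,
        t_dicrotic=t_dic,
        amp_sys=amp_sys,
        amp_refl=refl_ratio * amp_sys,
        amp_dicrotic=float(np.clip(rng.normal(0.16, 0.03), 0.03, 0.30)) * amp_sys,
        width_sys=0.055 * period,
        width_refl=0.075 * period,
        width_dicrotic=0.055 * period,
        noise_sd=0.01,
        baseline_drift_amp=0.04,
        drift_freq_hz=0.25,
        drift_phase=float(rng.uniform(0, 2 * np.pi)),
    )
    params.validate()
    sex = "M" if rng.random() < 0.5 else "F"
    return SubjectProfile(
        subject_id=subject_id, bp_class=bp_class, sbp=float(sbp), dbp=float(dbp),
        heart_rate=hr, pulse_params=params,
        age=int(rng.integers(21, 86)), sex=sex,
        height_cm=round(float(rng.normal(163, 8)), 1),
        weight_kg=round(float(np.clip(rng.normal(62, 15), 38, 120)), 1),
    )


def synthesize_beat(params: PulseParams, period: float, fs: float) -> np.ndarray:
    """One noiseless beat: sum of three Gaussian bumps on [0, period)."""
    if period <= 0 or fs <= 0:
        raise ValueError("period and fs must be positive")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if period <= params.t_dicrotic:
        raise ValueError("beat period must exceed the dicrotic component center")
    t = np.arange(int(round(period * fs))) / fs
    beat = np.zeros_like(t)
    for mu, amp, w in [
        (params.t_sys, params.amp_sys, params.width_sys),
        (params.t_refl, params.amp_refl, params.width_refl),
        (params.t_dicrotic, params.amp_dicrotic, params.width_dicrotic),
    ]:
        beat += amp * np.exp(-0.5 * ((t - mu) / w) ** 2)
    return beat


def analytic_beat(params: PulseParams):
    """Closed-form beat value and its first two derivatives as callables.

    Independent of the sampled/differenced pipeline; used as a fiducial oracle.
    """
    comps = [
        (params.t_sys, params.amp_sys, params.width_sys),
        (params.t_refl, params.amp_refl, params.width_refl),
        (params.t_dicrotic, params.amp_dicrotic, params.width_dicrotic),
    ]

    def f(t):
        t = np.asarray(t, dtype=float)
        return sum(a * np.exp(-0.5 * ((t - mu) / w) ** 2) for mu, a, w in comps)

    def df(t):
        t = np.asarray(t, dtype=float)
        return sum(-a * (t - mu) / w**2 * np.exp(-0.5 * ((t - mu) / w) ** 2)
                   for mu, a, w in comps)

    def d2f(t):
        t = np.asarray(t, dtype=float)
        return sum(a * (((t - mu) / w**2) ** 2 - 1.0 / w**2)
                   * np.exp(-0.5 * ((t - mu) / w) ** 2) for mu, a, w in comps)

    return f, df, d2f


def quantize(x: np.ndarray) -> np.ndarray:
    """Map a record onto the 12-bit integer grid spanned by its own range."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x, dtype=np.int64)
    return np.round((x - lo) / (hi - lo) * (ADC_LEVELS - 1)).astype(np.int64)


def synthesize_record(profile: SubjectProfile, duration: float, fs: float,
                      rng: np.random.Generator, record_index: int = 0) -> RawRecord:
    """Tile beats at the profile heart rate, add noise + drift, quantise."""
    period = profile.beat_period
    if duration <= period:
        raise ValueError("duration must exceed one beat period")
    p = profile.pulse_params
    beat = synthesize_beat(p, period, fs)
    n = int(round(duration * fs))
    # start 10% of a period before an onset so the first beat's onset minimum
    # is interior to the record (detectable)
    lead = int(0.9 * len(beat))
    reps = int(np.ceil((n + lead) / len(beat)))
    x = np.tile(beat, reps)[lead:lead + n].astype(float)
    t = np.arange(n) / fs
    if p.baseline_drift_amp > 0:
        x = x + p.baseline_drift_amp * np.sin(
            2 * np.pi * p.drift_freq_hz * t + p.drift_phase + record_index)
    if p.noise_sd > 0:
        x = x + rng.normal(0.0, p.noise_sd, size=n)
    return RawRecord(subject_id=profile.subject_id, record_index=record_index,
                     samples=quantize(x), fs=fs)


def generate_cohort(n_norm: int, n_pre: int, n_hyp: int, seed: int, *,
                    duration: float = 2.1, fs: float = 1000.0,
                    records_per_subject: int = 3, effect_scale: float = 1.0,
                    ) -> tuple[list[RawRecord], pd.DataFrame]:
    """Generate a full cohort: per-subject records plus a metadata table.

    Deterministic given ``seed`` (per-subject substreams spawned from one
    root ``SeedSequence``).
    """
    if min(n_norm, n_pre, n_hyp) < 0:
        raise ValueError("cohort sizes must be >= 0")
    classes = (["normotensive"] * n_norm + ["prehypertensive"] * n_pre
               + ["hypertensive"] * n_hyp)
    seeds = np.random.SeedSequence(seed).spawn(len(classes))
    records: list[RawRecord] = []
    meta_rows = []
    for i, (cls, ss) in enumerate(zip(classes, seeds)):
        rng = np.random.default_rng(ss)
        profile = sample_subject(cls, rng, subject_id=f"{i + 1:04d}",
                                 effect_scale=effect_scale)
        for k in range(records_per_subject):
            records.append(synthesize_record(profile, duration, fs, rng,
                                             record_index=k))
        meta_rows.append({
            "subject_id": profile.subject_id, "age": profile.age,
            "sex": profile.sex, "height_cm": profile.height_cm,
            "weight_kg": profile.weight_kg,
            "sbp": profile.sbp, "dbp": profile.dbp,
        })
    cols = ["subject_id", "age", "sex", "height_cm", "weight_kg", "sbp", "dbp"]
    meta = pd.DataFrame(meta_rows, columns=cols)
    return records, meta
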