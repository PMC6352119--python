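"""Shared fixtures: canonical beat parameters, noiseless waveforms, cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ppght import preprocess, synth
from ppght.types import PulseParams, SubjectProfile


def make_params(period: float = 0.8, *, refl_gap: float = 0.28,
                refl_ratio: float = 0.34, noise_sd: float = 0.0,
                drift: float = 0.0) -> PulseParams:
    """Canonical 3-Gaussian beat parameters scaled to a beat period."""
    t_sys = 0.20 * period
    return PulseParams(
        t_sys=t_sys,
        t_refl=t_sys + refl_gap * period,
        t_dicrotic=t_sys + (refl_gap + 0.22) * period,
        amp_sys=1.0,
        amp_refl=refl_ratio,
        amp_dicrotic=0.16,
        width_sys=0.055 * period,
        width_refl=0.075 * period,
        width_dicrotic=0.055 * period,
        noise_sd=noise_sd,
        baseline_drift_amp=drift,
    )


def make_profile(bp_class: str = "normotensive", hr: float = 75.0,
                 **param_kwargs) -> SubjectProfile:
    period = 60.0 / hr
    return SubjectProfile(
        subject_id="t0", bp_class=bp_class, sbp=110.0, dbp=70.0,
        heart_rate=hr, pulse_params=make_params(period, **param_kwargs))


def tiled_wave(params: PulseParams, period: float = 0.8, fs: float = 1000.0,
               n_beats: int = 4, lead_frac: float = 0.9):
    """Noiseless tiled beats -> WaveformSet (no bandpass, clean derivatives)."""
    beat = synth.synthesize_beat(params, period, fs)
    lead = int(lead_frac * len(beat))
    x = np.tile(beat, n_beats + 2)[lead:lead + int(n_beats * period * fs)]
    return preprocess.build_waveform_set(x, fs, filtered=False)


@pytest.fixture(scope="session")
def fixture_params() -> PulseParams:
    return make_params()


@pytest.fixture(scope="session")
def clean_wave(fixture_params):
    return tiled_wave(fixture_params)


@pytest.fixture(scope="session")
def small_cohort():
    return synth.generate_cohort(6, 6, 6, seed=11)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    from ppght.pipeline_io import extract_cohort_features

    records, meta = small_cohort
    return extract_cohort_features(records, meta)

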