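# ppght

A tested, reusable pipeline for hypertension risk stratification from
single-channel fingertip PPG morphology:

1. **synth** — synthetic cohorts of short PPG records (3-Gaussian beat model:
   systolic + reflected + dicrotic components; class-dependent reflected-wave
   timing/amplitude; 1 kHz, 12-bit, 2.1 s, three records per subject) plus a
   subject metadata table.
2. **preprocess** — skewness signal-quality index to pick each subject's best
   record, zero-phase fourth-order Chebyshev-II 0.5–10 Hz bandpass, and
   central-difference first/second/third derivatives (VPG/APG/jerk).
3. **fiducials** — beat segmentation and delineation of O/S/N/D on the PPG,
   w/x/y/z on the VPG and a/b/c/d/e on the APG, with level projection
   (e.g. c−2 = PPG value at the APG c-wave time).
4. **features** — a 125-entry morphological catalogue in seven categories
   (23 time spans, 14 PPG amplitudes, 10 VPG/APG values, 4 waveform areas,
   15 power areas, 43 ratios, 16 slopes), evaluated per beat, median-aggregated
   per subject, and z-scored per cohort. The catalogue ships as inspectable
   JSON (`src/ppght/data/catalogue.json`).
5. **selection** — six filter rankings (Spearman, ReliefF, information gain,
   chi-square, mRMR, Gini impurity reduction) and an SBP correlation report.
6. **stratify** — BP-class assignment (120/140 SBP, 80/90 DBP cutoffs), four
   classifiers (LDA, logistic regression, cubic SVM, weighted KNN with K=10),
   stratified 10-fold CV with per-fold selection refit (no leakage), and
   SE/PP/F1 reporting for the three pairings (norm-vs-pre, norm-vs-hyp,
   norm+pre-vs-hyp).
7. **pipeline_io** — plain-text signal/CSV/JSON readers and writers, run
   configuration, and end-to-end orchestration.

## CLI

```bash
# generate a synthetic cohort (plain-text records + metadata.csv)
ppght simulate --n-norm 48 --n-pre 41 --n-hyp 35 --seed 17 --out data/

# per-subject best-record selection + filtering -> waveform CSVs
ppght preprocess --in data/ --fs 1000 --out waves/

# 125-feature table
ppght extract --signals data/ --meta data/metadata.csv --out features.csv

# feature rankings for one pairing
ppght select --features features.csv --methods all --k 10 --seed 17 --out rankings.json

# full pairing x method x classifier CV grid
ppght classify --features features.csv --k 10 --seed 17 --out report.json

# everything end to end from a config file (JSON or "key: value" lines)
ppght run --config cfg.json --out results/
```

## Reproducibility

All randomness flows from explicit seeds (one root seed split into per-subject
substreams in the generator; seeded stratified shuffles in CV). Same seed in,
byte-identical CSV/JSON out — asserted by the test suite.
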