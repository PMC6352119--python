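"""Readers/writers, run configuration and end-to-end orchestration.

Signal files are plain text, one integer sample per line, named
``<subject>_<k>.txt`` (k = 0-based record index); the metadata table is a CSV
with header ``subject_id,age,sex,height_cm,weight_kg,sbp,dbp``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataFormatError
from .types import RawRecord, RankingResult

log = logging.getLogger(__name__)

_SIGNAL_FILE_RE = re.compile(r"^(?P<subject>.+)_(?P<idx>\d+)\.(txt|csv)$")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Fully-resolved pipeline parameters; defaults follow the acquisition
    and analysis settings the pipeline models (1 kHz, 0.5–10 Hz order-4
    band, K=10 neighbours, top-10 subset, 10 folds)."""

    fs: float = 1000.0
    band_low: float = 0.5
    band_high: float = 10.0
    filter_order: int = 4
    stopband_db: float = 40.0
    n_bins: int = 10
    k_neighbors: int = 10
    top_k: int = 10
    n_folds: int = 10
    seed: int = 17
    duration: float = 2.1
    n_norm: int = 48
    n_pre: int = 41
    n_hyp: int = 35
    effect_scale: float = 1.0
    global_selection: bool = False
    methods: tuple = ("spearman", "relieff", "info_gain", "chi2", "mrmr", "gini")
    classifiers: tuple = ("lda", "logistic", "cubic_svm", "weighted_knn")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["classifiers"] = list(self.classifiers)
        return d


def validate_config(cfg: Optional[RunConfig | dict] = None) -> RunConfig:
    """Fill defaults, check ranges; raise ConfigError listing all violations."""
    if cfg is None:
        cfg = RunConfig()
    elif isinstance(cfg, dict):
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        base = RunConfig().to_dict()
        base.update(cfg)
        base["methods"] = tuple(base["methods"])
        base["classifiers"] = tuple(base["classifiers"])
        cfg = RunConfig(**base)
    problems = []
    if cfg.fs <= 2 * cfg.band_high:
        problems.append(f"fs={cfg.fs} too low for band_high={cfg.band_high}")
    if not 0 < cfg.band_low < cfg.band_high:
        problems.append(f"band edges inverted or non-positive: "
                        f"[{cfg.band_low}, {cfg.band_high}]")
    if cfg.filter_order < 1:
        problems.append("filter_order must be >= 1")
    if cfg.n_folds < 2:
        problems.append("n_folds must be >= 2")
    if cfg.top_k < 1:
        problems.append("top_k must be >= 1")
    if cfg.n_bins < 2:
        problems.append("n_bins must be >= 2")
    if cfg.duration <= 0:
        problems.append("duration must be positive")
    if min(cfg.n_norm, cfg.n_pre, cfg.n_hyp) < 0:
        problems.append("cohort sizes must be >= 0")
    if problems:
        raise ConfigError("; ".join(problems))
    log.info("resolved config: %s", cfg.to_dict())
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Read a JSON or plain ``key: value`` config file."""
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        data = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ConfigError(f"unparseable config line: {line!r}")
            key, val = (s.strip() for s in line.split(":", 1))
            if key in ("methods", "classifiers"):
                data[key] = [v.strip() for v in val.split(",") if v.strip()]
            else:
                try:
                    data[key] = json.loads(val)
                except json.JSONDecodeError:
                    data[key] = val
    return validate_config(data)


# ---------------------------------------------------------------------------
# signal I/O

def write_signal_dir(records: Sequence[RawRecord], meta: pd.DataFrame,
                     outdir: str | Path) -> None:
    """Write per-record one-sample-per-line text files plus the metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        path = outdir / f"{rec.subject_id}_{rec.record_index}.txt"
        np.savetxt(path, np.asarray(rec.samples), fmt="%d")
    meta.to_csv(outdir / "metadata.csv", index=False)


def read_signal_dir(path: str | Path, fs: float = 1000.0) -> list[RawRecord]:
    """Parse ``<subject>_<k>.txt`` files; unparseable files are skipped with a
    warning.  Subjects are ordered by (subject_id, record_index)."""
    path = Path(path)
    if not path.is_dir():
        raise DataFormatError(f"not a directory: {path}")
    records = []
    for f in sorted(path.iterdir()):
        m = _SIGNAL_FILE_RE.match(f.name)
        if m is None:
            continue
        try:
            samples = np.loadtxt(f, ndmin=1, delimiter=None if f.suffix == ".txt" else ",")
        except (ValueError, OSError) as exc:
            log.warning("skipping unparseable signal file %s: %s", f.name, exc)
            continue
        if samples.ndim != 1 or samples.size == 0:
            log.warning("skipping non-1D/empty signal file %s", f.name)
            continue
        records.append(RawRecord(subject_id=m.group("subject"),
                                 record_index=int(m.group("idx")),
                                 samples=samples, fs=fs))
    if not records:
        raise DataFormatError(f"no parseable signal files under {path}")
    records.sort(key=lambda r: (r.subject_id, r.record_index))
    return records


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "sbp", "dbp"}
    missing = required - set(meta.columns)
    if missing:
        raise DataFormatError(f"metadata missing columns: {sorted(missing)}")
    return meta


def group_by_subject(records: Sequence[RawRecord]) -> dict[str, list[RawRecord]]:
    out: dict[str, list[RawRecord]] = {}
    for rec in records:
        out.setdefault(rec.subject_id, []).append(rec)
    for recs in out.values():
        recs.sort(key=lambda r: r.record_index)
    return out


# ---------------------------------------------------------------------------
# rankings / report serialisation

def rankings_to_json(rankings: dict[str, RankingResult]) -> str:
    return json.dumps({m: {"ordered": r.ordered_features, "scores": r.scores}
                       for m, r in rankings.items()}, indent=1)


def rankings_from_json(text: str) -> dict[str, RankingResult]:
    data = json.loads(text)
    return {m: RankingResult(method=m, ordered_features=d["ordered"],
                             scores=d["scores"]) for m, d in data.items()}


# ---------------------------------------------------------------------------
# orchestration

def extract_cohort_features(records: Sequence[RawRecord], meta: pd.DataFrame,
                            cfg: Optional[RunConfig] = None) -> pd.DataFrame:
    """records + metadata -> subjects × 125 feature table (raw, unnormalized)."""
    from . import features, fiducials, preprocess

    cfg = validate_config(cfg)
    per_subject = {}
    for sid, recs in group_by_subject(records).items():
        _, wave = preprocess.preprocess_subject(
            recs, band=(cfg.band_low, cfg.band_high), order=cfg.filter_order,
            stopband_db=cfg.stopband_db)
        beats = fiducials.delineate(wave)
        per_subject[sid] = features.extract_features(wave, beats)
    return features.build_feature_table(per_subject, meta)


def run_pipeline(cfg: Optional[RunConfig] = None, *,
                 outdir: Optional[str | Path] = None) -> dict:
    """simulate -> preprocess -> extract -> select -> classify, end to end.

    Returns the resolved config, the raw feature table, the SBP correlation
    report and the CV report; writes CSV/JSON artifacts when ``outdir`` is
    given.
    """
    from . import selection, stratify, synth

    cfg = validate_config(cfg)
    records, meta = synth.generate_cohort(
        cfg.n_norm, cfg.n_pre, cfg.n_hyp, cfg.seed, duration=cfg.duration,
        fs=cfg.fs, effect_scale=cfg.effect_scale)
    table = extract_cohort_features(records, meta, cfg)

    corr = selection.correlation_report(table)
    results = stratify.run_experiment(
        table, methods=cfg.methods, classifiers=cfg.classifiers, k=cfg.top_k,
        seed=cfg.seed, n_folds=cfg.n_folds, global_selection=cfg.global_selection,
        selection_kwargs={"n_bins": cfg.n_bins, "k_neighbors": cfg.k_neighbors})
    report = stratify.report_frame(results)

    out = {"config": cfg.to_dict(), "table": table, "correlation": corr,
           "report": report}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "features.csv", index=False)
        corr.to_csv(outdir / "correlation.csv", index=False)
        report.to_csv(outdir / "report.csv", index=False)
        payload = {"config": cfg.to_dict(),
                   "report": report.to_dict(orient="records")}
        (outdir / "report.json").write_text(json.dumps(payload, indent=1))
    return out
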