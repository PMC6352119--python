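"""BP-class assignment, classifiers, stratified 10-fold CV and SE/PP/F1 reporting.

Three pairwise experiments are supported: normotensive vs prehypertensive,
normotensive vs hypertensive, and normotensive+prehypertensive vs
hypertensive; the higher-BP group is always the positive class.  Feature
z-scoring and feature ranking are refit inside each training fold by default
(no leakage); a global-selection switch ranks once on the full table instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .types import BP_CLASSES

log = logging.getLogger(__name__)

CLASSIFIERS = ("lda", "logistic", "cubic_svm", "weighted_knn")

PAIRINGS = {
    "norm_vs_pre": (("normotensive",), ("prehypertensive",)),
    "norm_vs_hyp": (("normotensive",), ("hypertensive",)),
    "normpre_vs_hyp": (("normotensive", "prehypertensive"), ("hypertensive",)),
}


def assign_bp_class(sbp: float, dbp: float) -> str:
    """Map (SBP, DBP) in mmHg to a BP class.

    Hypertensive if SBP >= 140 or DBP >= 90; else prehypertensive if
    SBP >= 120 or DBP >= 80; else normotensive.  Precedence resolves the
    boundary overlap at 140/90.
    """
    if not (40 <= sbp <= 300) or not (20 <= dbp <= 200):
        raise ValueError(f"blood pressure out of physiologic range: SBP={sbp}, DBP={dbp}")
    if sbp >= 140 or dbp >= 90:
        return "hypertensive"
    if sbp >= 120 or dbp >= 80:
        return "prehypertensive"
    return "normotensive"


# ---------------------------------------------------------------------------
# metrics

def f1_from_percent(pp: float, se: float) -> float:
    """Harmonic mean of positive predictivity and sensitivity (both in %)."""
    if pp + se == 0:
        return 0.0
    return 2.0 * pp * se / (pp + se)


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    se = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    pp = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    return {"SE": se, "PP": pp, "F1": f1_from_percent(pp, se)}


# ---------------------------------------------------------------------------
# classifiers

class _WeightedKNN:
    """K-nearest-neighbour vote with inverse-squared-distance weights.

    Exact matches (zero distance) dominate: if any neighbour coincides with
    the query point, only the coincident neighbours vote.
    """

    def __init__(self, k: int = 10):
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray):
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X), dtype=self._y.dtype)
        k = min(self.k, len(self._X))
        for i, q in enumerate(X):
            d = np.sqrt(np.sum((self._X - q) ** 2, axis=1))
            nn = np.argsort(d, kind="stable")[:k]
            dn = d[nn]
            if np.any(dn == 0):
                votes = self._y[nn[dn == 0]]
                weights = np.ones(len(votes))
            else:
                votes = self._y[nn]
                weights = 1.0 / dn**2
            classes = np.unique(votes)
            tally = np.array([weights[votes == c].sum() for c in classes])
            out[i] = classes[int(np.argmax(tally))]
        return out


def make_classifier(name: str, seed: Optional[int] = None, *, knn_k: int = 10,
                    svm_c: float = 1.0):
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "logistic":
        # unpenalized maximum likelihood (C=inf); iteration cap guards divergence
        # on separable folds
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    if name == "cubic_svm":
        return SVC(kernel="poly", degree=3, C=svm_c, gamma="scale", coef0=1.0,
                   random_state=seed)
    if name == "weighted_knn":
        return _WeightedKNN(k=knn_k)
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


def fit_predict(classifier: str, X_train: np.ndarray, y_train: np.ndarray,
                X_test: np.ndarray, seed: Optional[int] = None) -> np.ndarray:
    """Train one classifier on the training split and label the test split."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training fold contains a single class")
    clf = make_classifier(classifier, seed)
    clf.fit(np.asarray(X_train, dtype=float), np.asarray(y_train))
    return np.asarray(clf.predict(np.asarray(X_test, dtype=float)))


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVResult:
    pairing: str
    method: str
    classifier: str
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0
    predictions: dict = field(default_factory=dict)  # subject_id -> 0/1
    folds: int = 10

    @property
    def metrics(self) -> dict[str, float]:
        return confusion_metrics(self.TP, self.FP, self.FN, self.TN)

    def as_row(self) -> dict:
        row = {"pairing": self.pairing, "method": self.method,
               "classifier": self.classifier, "TP": self.TP, "FP": self.FP,
               "FN": self.FN, "TN": self.TN}
        row.update({k: round(v, 2) for k, v in self.metrics.items()})
        return row


def pairing_labels(table: pd.DataFrame, pairing: str) -> pd.Series:
    """Binary labels on the pairing's subset: 1 = higher-BP (positive) group."""
    try:
        neg, pos = PAIRINGS[pairing]
    except KeyError:
        raise ValueError(f"unknown pairing {pairing!r}") from None
    cls = table["bp_class"]
    mask = cls.isin(neg + pos)
    return cls[mask].isin(pos).astype(int)


def _zscore_fold(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = np.nanmean(train, axis=0)
    sd = np.nanstd(train, axis=0)
    sd[sd == 0] = 1.0
    tr = (train - mean) / sd
    te = (test - mean) / sd
    # residual NaN (missing features) -> train-mean imputation, i.e. 0
    return np.nan_to_num(tr, nan=0.0), np.nan_to_num(te, nan=0.0)


def stratified_10fold(table: pd.DataFrame, pairing: str, method: str,
                      classifier: str, seed: int = 17, *, k: int = 10,
                      n_folds: int = 10, global_selection: bool = False,
                      selection_kwargs: Optional[dict] = None) -> CVResult:
    """One (pairing × method × classifier) cell with pooled confusion counts."""
    grid = run_experiment(table, methods=[method], classifiers=[classifier],
                          pairings=[pairing], k=k, seed=seed, n_folds=n_folds,
                          global_selection=global_selection,
                          selection_kwargs=selection_kwargs)
    return grid[0]


def run_experiment(table: pd.DataFrame, methods: Sequence[str],
                   classifiers: Sequence[str],
                   pairings: Optional[Sequence[str]] = None, *, k: int = 10,
                   seed: int = 17, n_folds: int = 10,
                   global_selection: bool = False,
                   selection_kwargs: Optional[dict] = None,
                   fixed_rankings: Optional[dict] = None) -> list[CVResult]:
    """Full grid over pairings × selection methods × classifiers.

    Folds are stratified with a seeded shuffle and shared across methods and
    classifiers within a pairing, so cells are comparable.  ``fixed_rankings``
    (method -> RankingResult) bypasses selection refitting entirely, e.g. for
    rankings loaded from a file.
    """
    from . import selection as sel

    selection_kwargs = dict(selection_kwargs or {})
    selection_kwargs.setdefault("mrmr_k", k)
    pairings = list(PAIRINGS) if pairings is None else list(pairings)
    results: list[CVResult] = []

    for pairing in pairings:
        y = pairing_labels(table, pairing)
        sub = table.loc[y.index].reset_index(drop=True)
        yv = y.to_numpy()
        n_min = int(np.bincount(yv).min())
        folds = n_folds
        if n_min < folds:
            log.warning("minority class has %d members; reducing folds to %d",
                        n_min, n_min)
            folds = n_min
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

        cells = {(m, c): CVResult(pairing, m, c, folds=folds)
                 for m in methods for c in classifiers}
        global_rankings = dict(fixed_rankings or {})
        if global_selection:
            for m in methods:
                global_rankings.setdefault(
                    m, sel.rank_features(sub, yv, m, **selection_kwargs))

        for tr_idx, te_idx in skf.split(np.zeros(len(yv)), yv):
            train, test = sub.iloc[tr_idx], sub.iloc[te_idx]
            y_tr, y_te = yv[tr_idx], yv[te_idx]
            for m in methods:
                if m in global_rankings:
                    ranking = global_rankings[m]
                else:
                    ranking = sel.rank_features(train, y_tr, m, **selection_kwargs)
                feats = ranking.top_k(k)
                Xtr_raw = train[feats].to_numpy(dtype=float)
                Xte_raw = test[feats].to_numpy(dtype=float)
                Xtr, Xte = _zscore_fold(Xtr_raw, Xte_raw)
                for c in classifiers:
                    pred = fit_predict(c, Xtr, y_tr, Xte, seed=seed)
                    cell = cells[(m, c)]
                    for sid, yp, yt in zip(test["subject_id"], pred, y_te):
                        cell.predictions[sid] = int(yp)
                        if yt == 1 and yp == 1:
                            cell.TP += 1
                        elif yt == 0 and yp == 1:
                            cell.FP += 1
                        elif yt == 1 and yp == 0:
                            cell.FN += 1
                        else:
                            cell.TN += 1
        results.extend(cells[(m, c)] for m in methods for c in classifiers)
    return results


def report_frame(results: Sequence[CVResult]) -> pd.DataFrame:
    """Tabular report; the best-F1 cell per pairing is flagged."""
    df = pd.DataFrame([r.as_row() for r in results])
    df["best"] = False
    for pairing, grp in df.groupby("pairing"):
        df.loc[grp["F1"].idxmax(), "best"] = True
    return df
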