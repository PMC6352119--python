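"""Filter-based feature ranking: Spearman, ReliefF, information gain,
chi-square, mRMR and Gini impurity reduction, plus the SBP correlation report.

All methods return a :class:`~ppght.types.RankingResult` whose ordering is a
permutation of the input feature columns (descending importance, ties broken
by input column order).  Discretizing methods use equal-frequency binning.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .features import feature_columns
from .types import RankingResult

log = logging.getLogger(__name__)

METHODS = ("spearman", "relieff", "info_gain", "chi2", "mrmr", "gini")


def _X(table: pd.DataFrame) -> pd.DataFrame:
    return table[feature_columns(table)]


def _order(scores: np.ndarray, names: Sequence[str], method: str) -> RankingResult:
    """Stable descending sort; NaN scores sink to the bottom."""
    s = np.where(np.isnan(scores), -np.inf, scores)
    idx = np.argsort(-s, kind="stable")
    return RankingResult(method=method,
                         ordered_features=[names[i] for i in idx],
                         scores=[float(scores[i]) for i in idx])


def _pairwise_drop(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = ~np.isnan(x)
    return x[m], y[m]


def _impute_median(X: pd.DataFrame) -> np.ndarray:
    M = X.to_numpy(dtype=float)
    med = np.nanmedian(M, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    idx = np.where(np.isnan(M))
    M[idx] = med[idx[1]]
    return M


def _equal_freq_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization codes (0..n_bins-1)."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="right")


def _entropy_bits(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _mi_bits(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (bits) between two small-integer code arrays."""
    _, a = np.unique(a, return_inverse=True)
    _, b = np.unique(b, return_inverse=True)
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (pa * pb))
    return float(np.nansum(terms))


def _encode_labels(labels) -> np.ndarray:
    _, y = np.unique(np.asarray(labels), return_inverse=True)
    return y


# ---------------------------------------------------------------------------
# correlation report

def correlation_report(table: pd.DataFrame, target: Optional[Sequence[float]] = None,
                       kind: str = "pearson") -> pd.DataFrame:
    """Per-feature correlation with SBP (default) plus two-sided p-value.

    Sorted by \\|r\\| descending.  Constant features are excluded with a log note.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 subjects for the correlation report")
    y_all = table["sbp"].to_numpy(dtype=float) if target is None else np.asarray(target, dtype=float)
    rows = []
    for name in feature_columns(table):
        x, y = _pairwise_drop(table[name].to_numpy(dtype=float), y_all)
        if x.size < 3 or np.ptp(x) == 0:
            log.info("correlation undefined for constant/empty feature %s", name)
            continue
        if kind == "pearson":
            r, p = stats.pearsonr(x, y)
        elif kind == "spearman":
            r, p = stats.spearmanr(x, y)
        else:
            raise ValueError(f"unknown correlation kind: {kind}")
        rows.append({"feature": name, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows, columns=["feature", "r", "p"])
    return out.reindex(out["r"].abs().sort_values(ascending=False, kind="stable").index
                       ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# ranking methods

def spearman_rank(table: pd.DataFrame, labels) -> RankingResult:
    """Score = |Spearman rho| between feature and the class label codes."""
    y_all = _encode_labels(labels).astype(float)
    names = feature_columns(table)
    scores = np.full(len(names), np.nan)
    for i, name in enumerate(names):
        x, y = _pairwise_drop(table[name].to_numpy(dtype=float), y_all)
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho = stats.spearmanr(x, y).statistic
        scores[i] = abs(rho)
    return _order(scores, names, "spearman")


def relieff(table: pd.DataFrame, labels, k_neighbors: int = 10,
            n_iters: Optional[int] = None,
            rng: Optional[np.random.Generator] = None) -> RankingResult:
    """ReliefF weights with k nearest hits/misses under Manhattan distance.

    Feature differences are range-normalized, so weights lie in [-1, 1].
    By default every instance is used once (deterministic); ``n_iters`` below
    n samples without replacement using ``rng``.
    """
    names = feature_columns(table)
    y = _encode_labels(labels)
    M = _impute_median(_X(table))
    n, d = M.shape
    span = np.ptp(M, axis=0)
    span[span == 0] = 1.0
    Mn = M / span  # per-feature range normalization

    classes, counts = np.unique(y, return_counts=True)
    priors = counts / n
    k_eff = min(k_neighbors, int(counts.min()) - 1)
    if k_eff < k_neighbors:
        log.warning("class smaller than k_neighbors: truncating k to %d", k_eff)
    if k_eff < 1:
        raise ValueError("each class must have more than 1 member")

    if n_iters is None or n_iters >= n:
        picks = np.arange(n)
    else:
        if rng is None:
            rng = np.random.default_rng()
        picks = rng.choice(n, size=n_iters, replace=False)

    D = cdist(Mn, Mn, metric="cityblock")
    np.fill_diagonal(D, np.inf)
    w = np.zeros(d)
    m = len(picks)
    for i in picks:
        ci = y[i]
        hit_idx = np.where(y == ci)[0]
        hit_idx = hit_idx[np.argsort(D[i, hit_idx], kind="stable")[:k_eff]]
        w -= np.abs(Mn[hit_idx] - Mn[i]).mean(axis=0) / m
        p_ci = priors[classes == ci][0]
        for cj, p_cj in zip(classes, priors):
            if cj == ci:
                continue
            miss_idx = np.where(y == cj)[0]
            miss_idx = miss_idx[np.argsort(D[i, miss_idx], kind="stable")[:k_eff]]
            w += (p_cj / (1 - p_ci)) * np.abs(Mn[miss_idx] - Mn[i]).mean(axis=0) / m
    return _order(w, names, "relieff")


def info_gain(table: pd.DataFrame, labels, n_bins: int = 10) -> RankingResult:
    """H(class) - H(class | equal-frequency-binned feature), in bits."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    names = feature_columns(table)
    y_all = _encode_labels(labels)
    scores = np.full(len(names), np.nan)
    for i, name in enumerate(names):
        x, y = _pairwise_drop(table[name].to_numpy(dtype=float), y_all)
        if x.size < 3:
            continue
        scores[i] = _mi_bits(_equal_freq_bins(x, n_bins), y)
    return _order(scores, names, "info_gain")


def chi_square(table: pd.DataFrame, labels, n_bins: int = 10) -> RankingResult:
    """Chi-square statistic of the binned-feature × class contingency table."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    names = feature_columns(table)
    y_all = _encode_labels(labels)
    scores = np.full(len(names), np.nan)
    for i, name in enumerate(names):
        x, y = _pairwise_drop(table[name].to_numpy(dtype=float), y_all)
        if x.size < 3:
            continue
        scores[i] = chi2_statistic(_equal_freq_bins(x, n_bins), y)
    return _order(scores, names, "chi2")


def chi2_statistic(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Pearson chi-square on the contingency table; empty rows/cols dropped."""
    _, a = np.unique(codes_a, return_inverse=True)
    _, b = np.unique(codes_b, return_inverse=True)
    obs = np.bincount(a * (b.max() + 1) + b,
                      minlength=(a.max() + 1) * (b.max() + 1)
                      ).reshape(a.max() + 1, b.max() + 1).astype(float)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    return float(np.sum((obs - exp) ** 2 / exp))


def mrmr(table: pd.DataFrame, labels, k: Optional[int] = None,
         n_bins: int = 10) -> RankingResult:
    """Greedy MID (mutual-information difference) ranking.

    The first ``k`` positions are the greedy picks (score = relevance minus
    mean redundancy at pick time); the remaining features are appended in
    relevance order so the result is a full permutation.
    """
    names = feature_columns(table)
    d = len(names)
    if k is None:
        k = d
    if k > d:
        raise ValueError("k exceeds the number of features")
    y = _encode_labels(labels)
    codes = np.column_stack([
        _equal_freq_bins(np.nan_to_num(table[n].to_numpy(dtype=float),
                                       nan=float(np.nanmedian(table[n])) if
                                       np.any(~np.isnan(table[n])) else 0.0), n_bins)
        for n in names])
    relevance = np.array([_mi_bits(codes[:, j], y) for j in range(d)])

    picked: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(d)
    remaining = list(range(d))
    for _ in range(k):
        if picked:
            objective = relevance - red_sum / len(picked)
        else:
            objective = relevance.copy()
        best = max(remaining, key=lambda j: (objective[j], -j))
        picked.append(best)
        scores.append(float(objective[best]))
        remaining.remove(best)
        for j in remaining:
            red_sum[j] += _mi_bits(codes[:, j], codes[:, best])
    # append leftovers by relevance so the permutation contract holds
    leftovers = sorted(remaining, key=lambda j: (-relevance[j], j))
    ordered = [names[j] for j in picked + leftovers]
    all_scores = scores + [float(relevance[j]) for j in leftovers]
    return RankingResult(method="mrmr", ordered_features=ordered, scores=all_scores)


def gini_index(table: pd.DataFrame, labels, n_bins: int = 10) -> RankingResult:
    """Gini impurity of the class prior minus bin-weighted conditional impurity."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    names = feature_columns(table)
    y_all = _encode_labels(labels)
    scores = np.full(len(names), np.nan)
    for i, name in enumerate(names):
        x, y = _pairwise_drop(table[name].to_numpy(dtype=float), y_all)
        if x.size < 3:
            continue
        scores[i] = _gini_reduction(_equal_freq_bins(x, n_bins), y)
    return _order(scores, names, "gini")


def _gini_impurity(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - np.sum(p**2))


def _gini_reduction(codes: np.ndarray, y: np.ndarray) -> float:
    prior = _gini_impurity(y)
    cond = 0.0
    for b in np.unique(codes):
        m = codes == b
        cond += m.mean() * _gini_impurity(y[m])
    return prior - cond


# ---------------------------------------------------------------------------

_DISPATCH = {
    "spearman": spearman_rank,
    "relieff": relieff,
    "info_gain": info_gain,
    "chi2": chi_square,
    "mrmr": mrmr,
    "gini": gini_index,
}


def rank_features(table: pd.DataFrame, labels, method: str, *,
                  n_bins: int = 10, k_neighbors: int = 10,
                  mrmr_k: Optional[int] = 10,
                  rng: Optional[np.random.Generator] = None) -> RankingResult:
    """Dispatch to one of the six ranking methods with its default knobs."""
    if method == "spearman":
        return spearman_rank(table, labels)
    if method == "relieff":
        return relieff(table, labels, k_neighbors=k_neighbors, rng=rng)
    if method == "info_gain":
        return info_gain(table, labels, n_bins=n_bins)
    if method == "chi2":
        return chi_square(table, labels, n_bins=n_bins)
    if method == "mrmr":
        if mrmr_k is not None:
            mrmr_k = min(mrmr_k, len(feature_columns(table)))
        return mrmr(table, labels, k=mrmr_k, n_bins=n_bins)
    if method == "gini":
        return gini_index(table, labels, n_bins=n_bins)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def top_k(result: RankingResult, k: int = 10) -> list[str]:
    return result.top_k(k)
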