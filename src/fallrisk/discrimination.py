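"""ROC analysis: AUC with DeLong confidence interval, the
sensitivity+specificity-maximizing (Youden) probability cutoff, and
10-fold cross-validated AUC from pooled out-of-fold probabilities.

A participant is classified positive when the score is >= the
threshold.  The curve itself comes from scikit-learn's cumulative
counting (all distinct thresholds retained); the DeLong variance and
the cross-validation machinery are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import Cohort
from .logistic import fit_logistic

__all__ = [
    "RocResult",
    "roc_curve",
    "auc_ci",
    "youden_cutoff",
    "crossval_auc",
]


@dataclass
class RocResult:
    """ROC curve points plus summary discrimination measures."""

    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: Optional[tuple[float, float]] = None
    best_cutoff: Optional[float] = None
    best_sens: Optional[float] = None
    best_spec: Optional[float] = None


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("labels must contain both classes, coded 0/1")
    return s, y


def roc_curve(scores, labels) -> RocResult:
    """ROC points over all distinct score thresholds, trapezoidal AUC.

    The AUC equals the Mann-Whitney probability that a random faller
    outscores a random non-faller, ties counting one half.
    """
    s, y = _validate(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr, auc=auc
    )


def _delong_variance(s: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via mid-rank placement values."""
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    # placements: P(neg < pos_i) and P(pos > neg_j), ties half weight
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else np.nan
    s01 = float(np.var(v01, ddof=1)) if n > 1 else np.nan
    return auc, s10 / m + s01 / n


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory DeLong interval for the AUC, truncated to [0, 1]."""
    s, y = _validate(scores, labels)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least two members of each class")
    auc, var = _delong_variance(s, y)
    if not np.isfinite(var) or var == 0.0:
        if len(np.unique(s)) == 1:
            raise ValueError("degenerate variance: all scores are tied")
        var = max(var, 0.0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def youden_cutoff(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity (Youden's J).

    Among tied maximizers the smallest candidate score is returned,
    with its sensitivity and specificity.
    """
    roc = roc_curve(scores, labels)
    finite = np.isfinite(roc.thresholds)
    thr = roc.thresholds[finite]
    sens = roc.sensitivity[finite]
    spec = roc.specificity[finite]
    j = sens + spec
    best = j >= j.max() - 1e-12
    # thresholds descend, so the last maximizer is the smallest candidate
    idx = np.where(best)[0][-1]
    return float(thr[idx]), float(sens[idx]), float(spec[idx])


def _partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random equal partition; the remainder is spread one per fold."""
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(perm[start:start + size])
        start += size
    return folds


def crossval_auc(
    cohort: Cohort,
    model_variables: Sequence[str],
    k: int = 10,
    seed: int = 0,
    fit_fn: Optional[Callable] = None,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Pooled k-fold cross-validated AUC with DeLong CI.

    Participants are clustered into ``k`` equal groups by random
    sampling without replacement; the model is refitted on each training
    complement and the out-of-fold probabilities are pooled into a
    single ROC/AUC.  Returns (auc, (lo, hi), pooled probabilities).
    """
    y = cohort.outcome
    n = len(y)
    rng = np.random.default_rng(seed)
    folds = None
    for _ in range(20):
        cand = _partition(n, k, rng)
        if all(len(f) > 0 and len(np.unique(y[f])) == 2 for f in cand):
            folds = cand
            break
    if folds is None:
        raise RuntimeError("could not build folds that retain both classes")
    if fit_fn is None:
        fit_fn = lambda c: fit_logistic(c, model_variables)  # noqa: E731
    pooled = np.empty(n)
    for f in folds:
        train = np.setdiff1d(np.arange(n), f)
        sub = Cohort(cohort.data.iloc[train].reset_index(drop=True), cohort.registry)
        m = fit_fn(sub)
        pooled[f] = np.atleast_1d(m.predict_proba(cohort.data.iloc[f]))
    auc = roc_curve(pooled, y).auc
    ci = auc_ci(pooled, y)
    return auc, ci, pooled
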