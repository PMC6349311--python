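"""ROC analysis at low false-positive rates.

The deployment policy recommends continuation of life-sustaining therapy only
above a score threshold chosen for a very low FPR, so the quantities of
interest are the TPR achievable under an FPR *bound* (conservative
convention: empirical FPR <= target) and bootstrap confidence intervals over
subjects.  Decisions use the strict rule "recommend iff score > threshold".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


def stratified_subject_folds(
    labels: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Deterministic stratified partition of subject indices into folds.

    If a class has fewer members than folds, the fold count is reduced with a
    warning rather than producing single-class training splits.
    """
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need both outcome classes to build stratified folds")
    min_count = min(int((labels == c).sum()) for c in classes)
    if min_count < n_folds:
        warnings.warn(
            f"smallest class has {min_count} subjects < {n_folds} folds; "
            f"reducing to {max(2, min_count)} folds", UserWarning,
        )
        n_folds = max(2, min_count)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in classes:
        idx = rng.permutation(np.flatnonzero(labels == c))
        for pos, i in enumerate(idx):
            folds[pos % n_folds].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


def _rates(scores: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[float, float]:
    pos = labels == 1
    tpr = float(np.mean(scores[pos] > threshold)) if pos.any() else np.nan
    fpr = float(np.mean(scores[~pos] > threshold)) if (~pos).any() else np.nan
    return tpr, fpr


def tpr_at_fpr_scores(
    scores: np.ndarray, labels: np.ndarray, fpr_target: float = 0.025
) -> tuple[float, float]:
    """Largest TPR whose empirical FPR is <= the target, with the realizing
    threshold (the most conservative one among ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not 0 < fpr_target < 1:
        raise ValueError("fpr_target must lie in (0, 1)")
    # candidate thresholds: every observed score (decision rule is strict >)
    candidates = np.unique(scores)
    best_tpr, best_thr = 0.0, float(scores.max())
    for thr in candidates:
        tpr, fpr = _rates(scores, labels, thr)
        if np.isnan(fpr) or fpr <= fpr_target:
            if tpr > best_tpr or (tpr == best_tpr and thr > best_thr):
                best_tpr, best_thr = tpr, float(thr)
    return best_tpr, best_thr


@dataclass
class RocResult:
    """Empirical ROC with stratified-bootstrap confidence bands."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    tnr: np.ndarray
    fnr: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    tpr_ci_low: np.ndarray
    tpr_ci_high: np.ndarray
    n_boot: int
    ci_method: str = "stratified subject bootstrap, percentile"
    scores: np.ndarray = field(default=None, repr=False)
    labels: np.ndarray = field(default=None, repr=False)
    seed: int = 0


def _bootstrap_indices(labels: np.ndarray, n_boot: int, rng: np.random.Generator):
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    for _ in range(n_boot):
        yield np.concatenate([rng.choice(pos, pos.size), rng.choice(neg, neg.size)])


def roc_with_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> RocResult:
    """Empirical ROC over all score thresholds with 95% bootstrap CIs.

    The bootstrap resamples subjects within each outcome class (stratified);
    per-point TPR bands are evaluated on the base curve's FPR grid with the
    conservative step convention.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes required for a ROC curve")
    if np.all(scores == scores[0]):
        warnings.warn("all scores identical; ROC curve is degenerate", RuntimeWarning)
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))

    rng = np.random.default_rng(seed)
    boot_aucs = np.empty(n_boot)
    boot_tpr = np.empty((n_boot, fpr.size))
    for b, idx in enumerate(_bootstrap_indices(labels, n_boot, rng)):
        s, y = scores[idx], labels[idx]
        if np.all(s == s[0]):
            boot_aucs[b] = 0.5
            boot_tpr[b] = fpr
            continue
        boot_aucs[b] = roc_auc_score(y, s)
        bf, bt, _ = roc_curve(y, s, drop_intermediate=False)
        # step interpolation: largest TPR at FPR <= grid value
        boot_tpr[b] = bt[np.searchsorted(bf, fpr, side="right") - 1]
    lo, hi = np.percentile(boot_aucs, [2.5, 97.5])
    tpr_lo, tpr_hi = np.percentile(boot_tpr, [2.5, 97.5], axis=0)
    return RocResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, tnr=1.0 - fpr, fnr=1.0 - tpr,
        auc=auc, auc_ci=(float(lo), float(hi)),
        tpr_ci_low=tpr_lo, tpr_ci_high=tpr_hi,
        n_boot=n_boot, scores=scores, labels=labels, seed=seed,
    )


def tpr_at_fpr(
    roc: RocResult, fpr_target: float = 0.025
) -> tuple[float, float, tuple[float, float]]:
    """TPR at an FPR bound, the realizing threshold, and its bootstrap CI."""
    t, thr = tpr_at_fpr_scores(roc.scores, roc.labels, fpr_target)
    rng = np.random.default_rng(roc.seed)
    boot = np.empty(roc.n_boot)
    for b, idx in enumerate(_bootstrap_indices(roc.labels, roc.n_boot, rng)):
        boot[b] = tpr_at_fpr_scores(roc.scores[idx], roc.labels[idx], fpr_target)[0]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return t, thr, (float(lo), float(hi))
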