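"""k-Nearest-Correlations classification with a defer-when-uncertain policy.

Each of a subject's canonical pairs votes through its k nearest labeled
pairs in the embedding: the vote q is the mean neighbor label.  Votes whose
class probability is not discriminative enough (|q - 0.5| <= t) are dropped,
and the subject score is the sum of log-odds of the remaining votes,

    score_p = sum_{i discriminative} log(q_i / (1 - q_i)),

with q clipped to [eps, 1 - eps] so votes of 0 or 1 stay finite (default
eps = 1/(2k), a Laplace-style stabilization that preserves vote ordering).
A subject with no discriminative vote — in particular one with no retained
correlation at all, or whose pairs have no neighbors inside the pruning
radius — is *deferred*: the system issues no recommendation for it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from .caa import CAAModel, CanonicalPair
from .metric import Embedding, build_embedding, neighbors_within, pairwise_distances
from .performance import stratified_subject_folds, tpr_at_fpr_scores

#: Sentinel score assigned to deferred subjects when ranking (below any log-odds sum).
DEFER_SCORE = -1e9

#: Default tuning grid: k in {1,3,5,7,9,15}, t in {0, 0.05, ..., 0.45}.
DEFAULT_GRID: list[tuple[int, float]] = [
    (k, round(0.05 * j, 2))
    for k, j in itertools.product((1, 3, 5, 7, 9, 15), range(10))
]

#: Reduced grid for desk-scale nested cross-validation runs.
SMALL_GRID: list[tuple[int, float]] = [
    (k, t) for k, t in itertools.product((1, 3, 5, 9), (0.0, 0.1, 0.2, 0.3))
]


@dataclass
class KNCConfig:
    k: int = 5
    t: float = 0.1
    epsilon: float | None = None  # None -> 1/(2k)
    prune_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.t < 0.5:
            raise ValueError("t must lie in [0, 0.5)")
        if self.epsilon is not None and not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.prune_radius <= 0:
            raise ValueError("prune_radius must be positive")

    @property
    def eps(self) -> float:
        return self.epsilon if self.epsilon is not None else 1.0 / (2.0 * self.k)


@dataclass
class CorrelationVote:
    q: float
    n_neighbors_used: int
    discriminative: bool


@dataclass
class SubjectScore:
    subject_id: str
    score: float
    m_p: int  # number of retained correlations for the subject
    n_discriminative: int
    deferred: bool


def correlation_vote(
    query: CanonicalPair, training: Embedding, cfg: KNCConfig,
    exclude_subject: str | None = None,
) -> CorrelationVote:
    """Class probability of one correlation structure from its k nearest
    labeled neighbors inside the pruning radius.

    Fewer than k neighbors: the available ones are used and counted.  Zero
    neighbors: the vote is non-discriminative regardless of t.
    """
    if any(p.label is None for p in training.points):
        raise ValueError("unlabeled training point encountered in vote")
    neigh = neighbors_within(training, query, cfg.k + len(training))  # over-fetch, trim below
    if exclude_subject is not None:
        neigh = [(p, d) for p, d in neigh if p.subject_id != exclude_subject]
    neigh = neigh[: cfg.k]
    if not neigh:
        return CorrelationVote(q=0.5, n_neighbors_used=0, discriminative=False)
    q = float(np.mean([p.label for p, _ in neigh]))
    return CorrelationVote(q=q, n_neighbors_used=len(neigh),
                           discriminative=abs(q - 0.5) > cfg.t)


def subject_score(
    votes: Sequence[CorrelationVote], cfg: KNCConfig, subject_id: str = "?"
) -> SubjectScore:
    """Thresholded log-odds aggregation over a subject's correlation votes."""
    disc = [v for v in votes if v.discriminative and v.n_neighbors_used > 0]
    if not disc:
        return SubjectScore(subject_id=subject_id, score=0.0, m_p=len(votes),
                            n_discriminative=0, deferred=True)
    eps = cfg.eps
    total = 0.0
    for v in disc:
        q = min(max(v.q, eps), 1.0 - eps)
        total += math.log(q / (1.0 - q))
    return SubjectScore(subject_id=subject_id, score=total, m_p=len(votes),
                        n_discriminative=len(disc), deferred=False)


def score_subject(
    pairs: Sequence[CanonicalPair], training: Embedding, cfg: KNCConfig,
    subject_id: str = "?",
) -> SubjectScore:
    """Vote every retained pair of one subject against the training embedding."""
    votes = [correlation_vote(p, training, cfg, exclude_subject=subject_id)
             for p in pairs]
    return subject_score(votes, cfg, subject_id=subject_id)


def predict_with_deferral(
    scores: Sequence[SubjectScore], threshold: float
) -> dict[str, str]:
    """Per-subject decision: recommend_positive iff not deferred and the score
    exceeds the operating threshold; everything else defers."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return {
        s.subject_id: (
            "recommend_positive" if (not s.deferred and s.score > threshold) else "defer"
        )
        for s in scores
    }


# ---------------------------------------------------------------------------
# hyperparameter tuning (inner cross-validation loop)
# ---------------------------------------------------------------------------

def _collect_points(models: Sequence[CAAModel], r2_min: float):
    """Flatten retained pairs into stacked arrays with subject indices."""
    U, V, subj_of_point = [], [], []
    for s, model in enumerate(models):
        for p in model.pairs:
            if p.r_squared > r2_min:
                U.append(p.u)
                V.append(p.v)
                subj_of_point.append(s)
    if U:
        return np.vstack(U), np.vstack(V), np.array(subj_of_point, dtype=int)
    return np.empty((0, 0)), np.empty((0, 0)), np.empty(0, dtype=int)


def _fold_scores(
    D, subj_of_point, labels, train_subjects, eval_subjects, ks, prune_radius,
):
    """q-votes for every evaluated subject's points against the training
    points, computed for all neighbor counts in ``ks`` at once via sorted
    prefix means.  Returns {subject: array (n_points, len(ks)) of q, counts}."""
    train_mask = np.isin(subj_of_point, train_subjects)
    cols = np.flatnonzero(train_mask)
    out = {}
    for s in eval_subjects:
        rows = np.flatnonzero(subj_of_point == s)
        qs = np.full((rows.size, len(ks)), 0.5)
        used = np.zeros((rows.size, len(ks)), dtype=int)
        for r, row in enumerate(rows):
            d = D[row, cols]
            within = d < prune_radius
            cand = cols[within]
            order = np.argsort(d[within], kind="stable")
            lab = labels[subj_of_point[cand[order]]].astype(float)
            if lab.size == 0:
                continue
            csum = np.cumsum(lab)
            for j, k in enumerate(ks):
                kk = min(k, lab.size)
                qs[r, j] = csum[kk - 1] / kk
                used[r, j] = kk
        out[s] = (qs, used)
    return out


def _aggregate(qs: np.ndarray, used: np.ndarray, t: float, eps: float) -> tuple[float, bool]:
    disc = (np.abs(qs - 0.5) > t) & (used > 0)
    if not disc.any():
        return 0.0, True
    q = np.clip(qs[disc], eps, 1.0 - eps)
    return float(np.sum(np.log(q / (1.0 - q)))), False


def tune_k_t(
    models: Sequence[CAAModel],
    labels: Sequence[int],
    grid: Sequence[tuple[int, float]] | None = None,
    inner_folds: int = 10,
    target_fpr: float = 0.025,
    prune_radius: float = 2.0,
    r2_min: float = 0.25,
    seed: int = 0,
) -> KNCConfig:
    """Select (k, t) by inner cross-validation on the training cohort.

    Criterion: maximize the mean inner-fold TPR at FPR <= target_fpr (the
    deployment operating regime); ties broken by pooled inner AUC, then
    smaller k, then smaller t.  Folds are split by subject so all of a
    subject's correlations stay together.
    """
    grid = list(grid) if grid is not None else list(DEFAULT_GRID)
    if not grid:
        raise ValueError("tuning grid must be nonempty")
    labels = np.asarray(labels, dtype=int)
    if len(grid) == 1:
        k, t = grid[0]
        return KNCConfig(k=k, t=t, prune_radius=prune_radius)

    U, V, subj_of_point = _collect_points(models, r2_min)
    n_subjects = len(models)
    ks = sorted({k for k, _ in grid})
    if U.size:
        D = pairwise_distances(U, V, U, V)
    else:
        D = np.empty((0, 0))

    folds = stratified_subject_folds(labels, inner_folds, seed)
    all_subjects = np.arange(n_subjects)
    # per grid point: list of fold TPRs, plus pooled out-of-fold scores
    fold_tprs = {g: [] for g in grid}
    pooled = {g: np.full(n_subjects, np.nan) for g in grid}
    for fold in folds:
        train = np.setdiff1d(all_subjects, fold)
        votes = _fold_scores(D, subj_of_point, labels, train, fold,
                             ks, prune_radius) if U.size else {}
        for k, t in grid:
            j = ks.index(k)
            cfg_eps = 1.0 / (2.0 * k)
            scores = np.full(fold.size, DEFER_SCORE)
            for i, s in enumerate(fold):
                if s in votes:
                    sc, deferred = _aggregate(votes[s][0][:, j], votes[s][1][:, j], t, cfg_eps)
                    if not deferred:
                        scores[i] = sc
                pooled[(k, t)][s] = scores[i]
            y = labels[fold]
            if np.unique(y).size < 2:
                continue  # fold cannot yield a TPR/FPR; stratification prevents this
            fold_tprs[(k, t)].append(tpr_at_fpr_scores(scores, y, target_fpr)[0])

    def key(g):
        k, t = g
        tprs = fold_tprs[g]
        mean_tpr = float(np.mean(tprs)) if tprs else 0.0
        p = pooled[g]
        ok = ~np.isnan(p)
        auc = roc_auc_score(labels[ok], p[ok]) if np.unique(labels[ok]).size == 2 else 0.5
        return (mean_tpr, auc, -k, -t)

    k, t = max(grid, key=key)
    return KNCConfig(k=k, t=t, prune_radius=prune_radius)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class KNearestCorrelations(BaseEstimator, ClassifierMixin):
    """Instance-set classifier over canonical autocorrelation embeddings.

    ``fit(X, y)`` takes one fitted :class:`~caekit.caa.CAAModel` per subject
    (the subject's set of canonical pairs) and binary outcome labels, and
    builds the labeled training embedding.  ``decision_function`` returns the
    thresholded log-odds score per subject (deferred subjects get ``-inf``);
    ``predict`` returns 1 for a positive recommendation and 0 otherwise
    (deferral folds into 0: the system stays silent rather than predicting
    the negative class).

    Parameters
    ----------
    k : int
        Neighbor count per correlation vote.
    t : float
        Discriminativeness threshold on |q - 0.5| in [0, 0.5).
    prune_radius : float
        Neighbor connections farther than this are discarded (default 2.0).
    epsilon : float or None
        Probability clip; None means 1/(2k).
    r2_min : float
        Admission filter on pair R^2 when building the embedding.
    threshold : float
        Operating threshold of the deferral policy used by ``predict``.
    """

    def __init__(self, k=5, t=0.1, prune_radius=2.0, epsilon=None,
                 r2_min=0.25, threshold=0.0):
        self.k = k
        self.t = t
        self.prune_radius = prune_radius
        self.epsilon = epsilon
        self.r2_min = r2_min
        self.threshold = threshold

    def _cfg(self) -> KNCConfig:
        return KNCConfig(k=self.k, t=self.t, epsilon=self.epsilon,
                         prune_radius=self.prune_radius)

    def fit(self, X: Sequence[CAAModel], y):
        y = np.asarray(y, dtype=int)
        if len(X) != y.size:
            raise ValueError("one label per subject model required")
        self.classes_ = np.unique(y)
        self.embedding_ = build_embedding(X, y.tolist(), r2_min=self.r2_min,
                                          prune_radius=self.prune_radius)
        return self

    def score_subjects(self, X: Sequence[CAAModel]) -> list[SubjectScore]:
        if not hasattr(self, "embedding_"):
            raise RuntimeError("classifier is not fitted")
        cfg = self._cfg()
        out = []
        for model in X:
            sid = model.subject_id if model.subject_id is not None else "?"
            pairs = [p for p in model.pairs if p.r_squared > self.r2_min]
            out.append(score_subject(pairs, self.embedding_, cfg, subject_id=sid))
        return out

    def decision_function(self, X: Sequence[CAAModel]) -> np.ndarray:
        return np.array([
            -np.inf if s.deferred else s.score for s in self.score_subjects(X)
        ])

    def predict(self, X: Sequence[CAAModel]) -> np.ndarray:
        scores = self.score_subjects(X)
        dec = predict_with_deferral(scores, self.threshold)
        return np.array([1 if dec[s.subject_id] == "recommend_positive" else 0
                         for s in scores])
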