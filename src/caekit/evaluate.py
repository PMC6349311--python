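"""Nested cross-validation harness.

Reproduces the study design: subject-stratified 10-fold outer
cross-validation with (k, t) tuned in an inner 10-fold loop within each
training fold, baselines (L1-regularized logistic regression and Euclidean
k-nn on quartile-set and last-point featurizations) evaluated on the
identical fold plan, ROC with bootstrap confidence intervals, and TPR at a
fixed low FPR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, PredefinedSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .caa import CAAModel, ForbiddenSets, SparsityConfig, fit_caa, standardize_columns
from .knc import (DEFER_SCORE, KNCConfig, _aggregate, _collect_points,
                  _fold_scores, tune_k_t)
from .metric import pairwise_distances
from .performance import (RocResult, roc_with_ci, stratified_subject_folds,
                          tpr_at_fpr, tpr_at_fpr_scores)

__all__ = [
    "FoldPlan", "make_folds", "run_cae_pipeline", "quartile_featurize",
    "last_point_featurize", "run_baselines", "roc_with_ci", "tpr_at_fpr",
    "tpr_at_fpr_scores", "RocResult", "summarize",
]


@dataclass
class FoldPlan:
    """Subject-level fold assignment shared by every evaluated method."""

    outer_folds: int
    inner_folds: int
    assignment: dict[str, int]  # subject_id -> outer fold
    seed: int

    def test_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def train_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f != fold)


def make_folds(
    labels: Mapping[str, int], outer_folds: int = 10, inner_folds: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Stratified subject-level folds, deterministic given the seed."""
    ids = sorted(labels)
    y = np.array([labels[s] for s in ids], dtype=int)
    folds = stratified_subject_folds(y, outer_folds, seed)
    assignment = {}
    for f, members in enumerate(folds):
        for i in members:
            assignment[ids[i]] = f
    return FoldPlan(outer_folds=len(folds), inner_folds=inner_folds,
                    assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# featurizations for the baselines
# ---------------------------------------------------------------------------

def quartile_featurize(X: np.ndarray) -> np.ndarray:
    """Q1, median, Q3 of every feature over the window (3m values,
    linear-interpolation quantile convention)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty window")
    q = np.quantile(X, [0.25, 0.5, 0.75], axis=0, method="linear")
    return q.T.ravel()


def last_point_featurize(X: np.ndarray) -> np.ndarray:
    """The final recorded row."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    return X[-1].copy()


# ---------------------------------------------------------------------------
# CAE pipeline
# ---------------------------------------------------------------------------

def fit_cohort_models(
    matrices: Sequence[np.ndarray],
    subject_ids: Sequence[str],
    config: SparsityConfig | None = None,
    forbidden: ForbiddenSets | None = None,
) -> list[CAAModel]:
    """Per-subject CAA fits (unsupervised, each on that subject's data only).

    Per-subject seeds are derived from ``config.seed`` so refits are
    deterministic regardless of cohort order.
    """
    config = config if config is not None else SparsityConfig()
    children = np.random.SeedSequence(config.seed).spawn(len(matrices))
    models = []
    for M, sid, child in zip(matrices, subject_ids, children):
        sub_cfg = SparsityConfig(**{**config.__dict__,
                                    "seed": int(child.generate_state(1)[0] % (2**31))})
        fm = standardize_columns(M)
        models.append(fit_caa(fm, sub_cfg, forbidden, subject_id=sid))
    return models


@dataclass
class PipelineResult:
    subject_ids: list[str]
    labels: np.ndarray
    scores: np.ndarray           # out-of-fold; DEFER_SCORE sentinel when deferred
    deferred: np.ndarray         # boolean
    tuned: list[KNCConfig]       # per outer fold
    models: list[CAAModel] = field(repr=False, default_factory=list)


def run_cae_pipeline(
    matrices: Sequence[np.ndarray],
    labels: Mapping[str, int],
    subject_ids: Sequence[str],
    plan: FoldPlan,
    caa_config: SparsityConfig | None = None,
    forbidden: ForbiddenSets | None = None,
    grid: Sequence[tuple[int, float]] | None = None,
    target_fpr: float = 0.025,
    prune_radius: float = 2.0,
    models: Sequence[CAAModel] | None = None,
) -> PipelineResult:
    """Out-of-fold CAE scores under the nested-CV design.

    For each outer fold the training embedding is built from training
    subjects only, (k, t) are tuned on inner subject folds of the training
    set, and the held-out subjects are scored against the training embedding.
    Pre-fitted per-subject models may be passed in (the per-subject CAA fit
    is unsupervised and uses no other subject's data, so it is fold-safe).
    """
    subject_ids = list(subject_ids)
    caa_config = caa_config if caa_config is not None else SparsityConfig()
    if models is None:
        models = fit_cohort_models(matrices, subject_ids, caa_config, forbidden)
    models = list(models)
    y = np.array([labels[s] for s in subject_ids], dtype=int)
    r2_min = caa_config.r2_min

    # one global distance matrix over all retained pairs; folds mask into it
    U, V, subj_of_point = _collect_points(models, r2_min)
    D = pairwise_distances(U, V, U, V) if U.size else np.empty((0, 0))

    idx_of = {s: i for i, s in enumerate(subject_ids)}
    scores = np.full(len(subject_ids), DEFER_SCORE)
    deferred = np.ones(len(subject_ids), dtype=bool)
    tuned: list[KNCConfig] = []
    for fold in range(plan.outer_folds):
        test_ids = plan.test_subjects(fold)
        train_ids = plan.train_subjects(fold)
        train_idx = np.array([idx_of[s] for s in train_ids], dtype=int)
        test_idx = np.array([idx_of[s] for s in test_ids], dtype=int)
        # leakage guard: tuning and embedding see training subjects only
        assert not set(test_ids) & set(train_ids)
        cfg = tune_k_t(
            [models[i] for i in train_idx], y[train_idx], grid=grid,
            inner_folds=plan.inner_folds, target_fpr=target_fpr,
            prune_radius=prune_radius, r2_min=r2_min, seed=plan.seed + fold,
        )
        tuned.append(cfg)
        votes = _fold_scores(D, subj_of_point, y, train_idx, test_idx,
                             [cfg.k], prune_radius) if U.size else {}
        for i in test_idx:
            if i in votes:
                sc, dfr = _aggregate(votes[i][0][:, 0], votes[i][1][:, 0],
                                     cfg.t, cfg.eps)
                if not dfr:
                    scores[i], deferred[i] = sc, False
    return PipelineResult(subject_ids=subject_ids, labels=y, scores=scores,
                          deferred=deferred, tuned=tuned, models=models)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

_BASELINES = {
    "logit_sets": ("logit", quartile_featurize),
    "logit_points": ("logit", last_point_featurize),
    "knn_sets": ("knn", quartile_featurize),
    "knn_points": ("knn", last_point_featurize),
}


def _baseline_estimator(kind: str, inner_cv, seed: int):
    if kind == "logit":
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(penalty="l1", solver="liblinear",
                                       max_iter=2000, random_state=seed)),
        ])
        grid = {"clf__C": [0.01, 0.1, 1.0, 10.0, 100.0]}
    elif kind == "knn":
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("clf", KNeighborsClassifier()),
        ])
        grid = {"clf__n_neighbors": [1, 3, 5, 7, 9, 15]}
    else:  # pragma: no cover
        raise ValueError(kind)
    return GridSearchCV(pipe, grid, cv=inner_cv, scoring="roc_auc", n_jobs=1)


def run_baselines(
    matrices: Sequence[np.ndarray],
    labels: Mapping[str, int],
    subject_ids: Sequence[str],
    plan: FoldPlan,
    methods: Sequence[str] = ("logit_sets", "logit_points", "knn_sets", "knn_points"),
) -> dict[str, np.ndarray]:
    """Out-of-fold probability scores for the baseline learners on the same
    fold plan as the CAE pipeline (paired comparison); hyperparameters are
    tuned in inner subject folds of each training fold."""
    subject_ids = list(subject_ids)
    y = np.array([labels[s] for s in subject_ids], dtype=int)
    idx_of = {s: i for i, s in enumerate(subject_ids)}
    feats = {
        name: np.vstack([_BASELINES[name][1](M) for M in matrices])
        for name in methods
    }
    out = {name: np.full(len(subject_ids), np.nan) for name in methods}
    for fold in range(plan.outer_folds):
        train_idx = np.array([idx_of[s] for s in plan.train_subjects(fold)], dtype=int)
        test_idx = np.array([idx_of[s] for s in plan.test_subjects(fold)], dtype=int)
        inner = stratified_subject_folds(y[train_idx], plan.inner_folds,
                                         plan.seed + fold)
        fold_of = np.empty(train_idx.size, dtype=int)
        for f, members in enumerate(inner):
            fold_of[members] = f
        inner_cv = PredefinedSplit(fold_of)
        for name in methods:
            kind = _BASELINES[name][0]
            X = feats[name]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gs = _baseline_estimator(kind, inner_cv, plan.seed)
                gs.fit(X[train_idx], y[train_idx])
            out[name][test_idx] = gs.predict_proba(X[test_idx])[:, 1]
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(
    scores_by_method: Mapping[str, np.ndarray],
    labels: np.ndarray,
    deferred_by_method: Mapping[str, np.ndarray] | None = None,
    fpr_targets: Sequence[float] = (0.025, 0.05),
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """AUC, TPR at the low-FPR operating points (with bootstrap CIs) and
    deferral rate per method."""
    out = {}
    for name, scores in scores_by_method.items():
        roc = roc_with_ci(np.asarray(scores, dtype=float), labels,
                          n_boot=n_boot, seed=seed)
        entry = {"auc": roc.auc, "auc_ci": list(roc.auc_ci)}
        for target in fpr_targets:
            t, thr, ci = tpr_at_fpr(roc, target)
            entry[f"tpr_at_fpr_{target}"] = t
            entry[f"tpr_at_fpr_{target}_ci"] = list(ci)
            entry[f"threshold_at_fpr_{target}"] = thr
        if deferred_by_method and name in deferred_by_method:
            entry["deferral_rate"] = float(np.mean(deferred_by_method[name]))
        out[name] = entry
    return out
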