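"""Canonical autocorrelation analysis (CAA).

CAA discovers sparse multiple-to-multiple linear correlations *within* a
single feature matrix X: it maximizes ``u^T X^T X v`` over unit vectors
``u, v`` under L1 budgets and a hard disjoint-support constraint, so each
solution is a two-dimensional projection ``(Xu, Xv)`` in which the data are
maximally correlated across two non-overlapping feature subsets.  The
biconvex problem is solved by alternate convex search; each half step is an
exactly-solved convex subproblem via weighted soft-thresholding derived from
the KKT conditions.  Multiple pairs are extracted by deflating the gram
matrix.  Forbidden-correlation sets generalize the disjointness constraint
to feature groups (e.g. a feature and its own polynomial powers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator


class DegenerateStepError(RuntimeError):
    """The thresholded gradient vanished: v's support dominates every correlate."""


class NoStructureError(RuntimeError):
    """Every restart of the alternating search degenerated; no pair found."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """One subject-epoch's n_timesteps x n_features data block."""

    values: np.ndarray
    feature_names: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("FeatureMatrix requires a 2-D array")
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise ValueError(f"need at least 2 rows and 2 columns, got {n}x{m}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in feature matrix")
        if len(self.feature_names) != m:
            raise ValueError("feature_names length does not match column count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def m_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class SparsityConfig:
    """Tuning knobs of the CAA optimizer.

    c1, c2 are the L1 budgets of u and v; feasibility with the unit L2
    constraint requires 1 <= c <= sqrt(m), and small values give sparser
    supports.  r2_min is the retention filter on the squared Pearson
    correlation of the projection scores; extraction stops at the first
    sub-threshold pair.
    """

    c1: float = 1.75
    c2: float = 1.75
    max_pairs: int = 5
    r2_min: float = 0.25
    tol: float = 1e-6
    max_iter: int = 500
    n_restarts: int = 4
    seed: int = 0

    def validate(self, m: int) -> None:
        root_m = np.sqrt(m)
        for name, c in (("c1", self.c1), ("c2", self.c2)):
            if not 1.0 <= c <= root_m + 1e-12:
                raise ValueError(f"{name}={c} outside feasible range [1, sqrt(m)={root_m:.4f}]")
        if not 0.0 <= self.r2_min < 1.0:
            raise ValueError("r2_min must lie in [0, 1)")
        if self.max_pairs < 1 or self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("max_pairs, max_iter and n_restarts must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


class ForbiddenSets:
    """Per-feature sets S_i of indices whose co-activation with i is forbidden.

    Stored as a symmetric boolean mask with a True diagonal: self-correlation
    is always forbidden, which reproduces the plain disjoint-support
    constraint as the default.
    """

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
            raise ValueError("forbidden mask must be square")
        # symmetric closure + mandatory self-forbidding
        self.mask = mask | mask.T
        np.fill_diagonal(self.mask, True)

    @classmethod
    def default(cls, m: int) -> "ForbiddenSets":
        return cls(np.eye(m, dtype=bool))

    @classmethod
    def from_groups(cls, m: int, groups: Iterable[Sequence[int]]) -> "ForbiddenSets":
        """Mutually forbid every pair of features inside each group."""
        mask = np.eye(m, dtype=bool)
        for g in groups:
            idx = np.asarray(list(g), dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= m):
                raise ValueError("group index out of range")
            mask[np.ix_(idx, idx)] = True
        return cls(mask)

    @property
    def m(self) -> int:
        return self.mask.shape[0]

    def sets(self) -> list[set[int]]:
        return [set(np.flatnonzero(row)) for row in self.mask]

    def weights(self, v: np.ndarray) -> np.ndarray:
        """w_i = sum_{j in S_i} |v_j| — the soft-threshold weights of Eq-4 form."""
        return self.mask @ np.abs(v)

    def violation(self, u: np.ndarray, v: np.ndarray) -> float:
        """sum_i sum_{j in S_i} |u_i v_j|; feasible pairs give exactly 0."""
        return float(np.abs(u) @ self.mask @ np.abs(v))


@dataclass
class ThresholdParams:
    """Multipliers of one KKT solve: lambda1 enforces disjointness, lambda2 the L1 budget."""

    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("threshold multipliers must be nonnegative")


@dataclass
class CanonicalPair:
    """One discovered correlation structure: unit vectors u, v with disjoint support."""

    u: np.ndarray
    v: np.ndarray
    d: float
    r_squared: float = float("nan")
    subject_id: str | None = None
    pair_index: int = 0
    iterations: int = 0
    restart_index: int = 0
    converged: bool = True
    objective_trace: list[float] = field(default_factory=list, repr=False, compare=False)

    def support(self, which: str = "u", rel_threshold: float = 0.0) -> set[int]:
        """Indices carrying weight; rel_threshold drops coordinates below that
        fraction of the largest magnitude (0 = exact nonzero support)."""
        x = np.abs(self.u if which == "u" else self.v)
        cut = rel_threshold * x.max() if x.max() > 0 else 0.0
        return {int(i) for i in np.flatnonzero(x > cut)}

    def validate(self, c1: float, c2: float, forbidden: ForbiddenSets) -> None:
        for name, x, c in (("u", self.u, c1), ("v", self.v, c2)):
            n2 = np.linalg.norm(x)
            if abs(n2 - 1.0) > 1e-8:
                raise AssertionError(f"||{name}||_2 = {n2} != 1")
            if np.abs(x).sum() > c * (1 + 1e-8):
                raise AssertionError(f"||{name}||_1 exceeds budget {c}")
        if forbidden.violation(self.u, self.v) != 0.0:
            raise AssertionError("forbidden-support constraint violated")
        i = int(np.argmax(np.abs(self.u)))
        if self.u[i] < 0:
            raise AssertionError("pair not sign-canonicalized")
        if self.d < 0:
            raise AssertionError("canonical correlation value d must be nonnegative")


@dataclass
class CAAModel:
    """Ordered canonical pairs extracted from one subject plus fit provenance."""

    pairs: list[CanonicalPair]
    config: SparsityConfig
    forbidden: ForbiddenSets
    objective_trace: list[list[float]]
    feature_names: list[str] = field(default_factory=list)
    subject_id: str | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def standardize_columns(M: np.ndarray, feature_names: Sequence[str] | None = None) -> FeatureMatrix:
    """Center each column and scale to unit sample variance (ddof=1).

    Constant columns are a hard error naming the offending columns; callers
    that prefer to drop them (the CLI does) must do so beforehand.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite entries in input matrix")
    names = list(feature_names) if feature_names is not None else [f"f{i:03d}" for i in range(M.shape[1])]
    sd = M.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        bad = ", ".join(names[i] for i in constant)
        raise ValueError(f"constant column(s) cannot be standardized: {bad}")
    Z = (M - M.mean(axis=0)) / sd
    return FeatureMatrix(Z, names, standardized=True)


def compute_lambda1(g: np.ndarray, v: np.ndarray, forbidden: ForbiddenSets) -> float:
    """Smallest multiplier whose weighted soft-threshold zeroes every coordinate
    forbidden by the support of v (coordinates with zero weight are unaffected)."""
    v = np.asarray(v, dtype=float)
    if not np.any(v):
        raise ValueError("v is identically zero; re-initialize")
    w = forbidden.weights(v)
    active = w > 0
    if not np.any(active):
        return 0.0
    return float(np.max(np.abs(g[active]) / w[active]))


def soft_threshold_weighted(g: np.ndarray, theta: np.ndarray | float) -> np.ndarray:
    """Coordinate-wise operator sign(g_i) * max(|g_i| - theta_i, 0)."""
    g = np.asarray(g, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("thresholds must be nonnegative")
    return np.sign(g) * np.maximum(np.abs(g) - theta, 0.0)


def kkt_solve_step(
    G: np.ndarray,
    v: np.ndarray,
    c: float,
    forbidden: ForbiddenSets,
) -> tuple[np.ndarray, ThresholdParams]:
    """Exact solution of one convex half-step of the alternating search.

    Maximizes ``u^T G v`` subject to ``||u||_2 <= 1``, ``||u||_1 <= c`` and
    support disjointness against v under the forbidden sets.  The maximizer is
    the L2-normalized weighted soft-threshold of the gradient ``g = G v``:
    lambda1 is set to the smallest value zeroing the forbidden coordinates and,
    when the L1 constraint is violated, lambda2 is found by bisection so that
    the normalized solution lands on the L1 budget.
    """
    g = G @ np.asarray(v, dtype=float)
    lam1 = compute_lambda1(g, v, forbidden)
    w = forbidden.weights(v)
    blocked = w > 0

    def candidate(lam2: float) -> tuple[np.ndarray | None, float]:
        s = soft_threshold_weighted(g, lam1 * w + lam2)
        s[blocked] = 0.0  # exact zeros on the forbidden support
        n2 = np.linalg.norm(s)
        if n2 == 0.0:
            return None, np.inf
        u = s / n2
        return u, float(np.abs(u).sum())

    u, l1 = candidate(0.0)
    # treat pure rounding residue (e.g. after deflation) as no gradient at all
    if u is None or np.max(np.abs(g) * ~blocked) <= 1e-12 * max(1.0, np.max(np.abs(g))):
        raise DegenerateStepError("thresholded gradient is identically zero")
    if l1 <= c * (1 + 1e-12):
        return u, ThresholdParams(lam1, 0.0)

    free = ~blocked
    if not np.any(np.abs(g[free]) > 0):  # pragma: no cover - caught above
        raise DegenerateStepError("no admissible gradient mass")
    lo, hi = 0.0, float(np.max(np.abs(g[free])))
    # l1 of the normalized thresholded gradient decreases continuously from
    # its lambda2=0 value (> c) to 1 (<= c since c >= 1): a crossing exists.
    best_u, best_lam2, best_l1 = None, hi, 1.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        u_mid, l1_mid = candidate(mid)
        if u_mid is None or l1_mid > c:
            # infeasible side (or all-zero): the crossing is above mid
            if u_mid is None:
                hi = mid
            else:
                lo = mid
        else:
            # feasible; keep the tightest feasible solution seen so far
            if best_u is None or l1_mid > best_l1:
                best_u, best_lam2, best_l1 = u_mid, mid, l1_mid
            hi = mid
        if hi - lo < 1e-15 * max(1.0, hi):
            break
    if best_u is None:
        raise RuntimeError(
            f"binary search failed to bracket the L1 budget: c={c}, "
            f"l1(0)={l1:.6f}, bracket=({lo}, {hi})"
        )
    if abs(best_l1 - c) > 1e-6:
        raise RuntimeError(
            f"binary search did not reach the L1 budget: |{best_l1:.8f} - {c}| > 1e-6"
        )
    return best_u, ThresholdParams(lam1, best_lam2)


def canonicalize_sign(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip (u, v) jointly so the largest-|.| coordinate of u is positive.

    (-u, -v) is objective-equivalent; the canonical representative stabilizes
    convergence checks and the embedding metric.  np.argmax breaks magnitude
    ties at the lowest index.
    """
    i = int(np.argmax(np.abs(u)))
    if u[i] < 0:
        return -u, -v
    return u, v


def _single_coordinate(m: int, j: int) -> np.ndarray:
    e = np.zeros(m)
    e[j] = 1.0
    return e


def alternate_convex_search(
    G: np.ndarray,
    config: SparsityConfig,
    forbidden: ForbiddenSets | None = None,
    v_init: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> CanonicalPair:
    """Alternate exact convex half-steps for u and v until the canonicalized
    iterates move less than ``config.tol`` in the sup norm, returning the best
    pair over the restarts.

    Restart 0 starts from the single coordinate carrying the largest loading
    of the leading eigenvector of G; the remaining restarts start from random
    single coordinates.  (A dense initializer is useless here: with every
    v_j != 0 the first half-step's disjointness threshold removes every
    coordinate.)  Raises NoStructureError when all restarts degenerate.
    """
    G = np.asarray(G, dtype=float)
    m = G.shape[0]
    if G.ndim != 2 or G.shape[1] != m:
        raise ValueError("G must be square")
    if m < 2:
        raise ValueError("need at least two features")
    forbidden = forbidden if forbidden is not None else ForbiddenSets.default(m)
    config.validate(m)
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    inits: list[np.ndarray] = []
    if v_init is not None:
        v0 = np.asarray(v_init, dtype=float)
        inits.append(v0 / np.linalg.norm(v0))
    else:
        lead = np.linalg.eigh(G)[1][:, -1]
        inits.append(_single_coordinate(m, int(np.argmax(np.abs(lead)))))
    n_random = max(0, config.n_restarts - len(inits))
    if n_random:
        pool = rng.permutation(m)
        taken = {int(np.argmax(v)) for v in inits if np.count_nonzero(v) == 1}
        coords = [j for j in pool if j not in taken]
        while len(coords) < n_random:
            coords.append(int(rng.integers(m)))
        inits.extend(_single_coordinate(m, int(j)) for j in coords[:n_random])

    best: CanonicalPair | None = None
    for r, v0 in enumerate(inits):
        try:
            u, v, trace, iters, converged = _run_restart(G, v0, config, forbidden)
        except DegenerateStepError:
            continue
        u, v = canonicalize_sign(u, v)
        d = float(u @ G @ v)
        if best is None or d > best.d:
            best = CanonicalPair(
                u=u, v=v, d=d, iterations=iters, restart_index=r,
                converged=converged, objective_trace=trace,
            )
    if best is None:
        raise NoStructureError("all restarts degenerated; no correlation structure found")
    return best


def _run_restart(
    G: np.ndarray,
    v0: np.ndarray,
    config: SparsityConfig,
    forbidden: ForbiddenSets,
) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
    v = v0
    u_prev = v_prev = None
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        u, _ = kkt_solve_step(G, v, config.c1, forbidden)
        trace.append(float(u @ G @ v))
        v, _ = kkt_solve_step(G, u, config.c2, forbidden)
        trace.append(float(u @ G @ v))
        cu, cv = canonicalize_sign(u, v)
        if u_prev is not None:
            delta = max(np.max(np.abs(cu - u_prev)), np.max(np.abs(cv - v_prev)))
            if delta < config.tol:
                converged = True
                u_prev, v_prev = cu, cv
                break
        u_prev, v_prev = cu, cv
    return u_prev, v_prev, trace, it, converged


def compute_r_squared(X: FeatureMatrix | np.ndarray, pair: CanonicalPair) -> float:
    """Squared Pearson correlation between the projection scores Xu and Xv."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    a = values @ pair.u
    b = values @ pair.v
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("zero-variance projection; R^2 reported as 0", RuntimeWarning)
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def deflate_gram(G: np.ndarray, pair: CanonicalPair) -> np.ndarray:
    """Remove a found correlation from the gram matrix: G - d(uv^T + vu^T)."""
    return G - pair.d * (np.outer(pair.u, pair.v) + np.outer(pair.v, pair.u))


def fit_caa(
    X: FeatureMatrix | np.ndarray,
    config: SparsityConfig | None = None,
    forbidden: ForbiddenSets | None = None,
    subject_id: str | None = None,
) -> CAAModel:
    """Extract canonical pairs sequentially with deflation.

    Extraction stops at max_pairs, on a degenerate step, or at the first pair
    whose projection R^2 fails the retention filter (that pair is discarded:
    deflating beyond noise-level pairs is meaningless).
    """
    if isinstance(X, FeatureMatrix):
        fm = X if X.standardized else standardize_columns(X.values, X.feature_names)
    else:
        fm = standardize_columns(X)
    config = config if config is not None else SparsityConfig()
    m = fm.m_cols
    forbidden = forbidden if forbidden is not None else ForbiddenSets.default(m)
    if forbidden.m != m:
        raise ValueError("forbidden sets dimension does not match feature count")
    config.validate(m)

    G = fm.values.T @ fm.values / (fm.n_rows - 1)
    rng = np.random.default_rng(config.seed)
    pairs: list[CanonicalPair] = []
    traces: list[list[float]] = []
    for k in range(config.max_pairs):
        try:
            pair = alternate_convex_search(G, config, forbidden, rng=rng)
        except NoStructureError:
            break
        pair.r_squared = compute_r_squared(fm, pair)
        pair.pair_index = k
        pair.subject_id = subject_id
        if pair.r_squared <= config.r2_min:
            break
        pairs.append(pair)
        traces.append(pair.objective_trace)
        G = deflate_gram(G, pair)
    return CAAModel(
        pairs=pairs, config=config, forbidden=forbidden,
        objective_trace=traces, feature_names=fm.feature_names,
        subject_id=subject_id,
    )


def expand_polynomial_features(
    X: FeatureMatrix, degree: int = 2
) -> tuple[FeatureMatrix, ForbiddenSets]:
    """Append re-standardized powers x^2..x^degree of each column.

    The returned ForbiddenSets places each original feature and all its powers
    in one mutual forbidden group, so a feature can never be "correlated" with
    its own powers — those relationships hold by construction.
    """
    if not X.standardized:
        raise ValueError("expand_polynomial_features expects a standardized matrix")
    if degree < 2:
        raise ValueError("degree must be >= 2")
    peak = float(np.max(np.abs(X.values)))
    if peak > 0 and degree * np.log10(peak) > 150:
        raise ValueError("powers would overflow; clip extreme values first")
    m = X.m_cols
    blocks = [X.values]
    names = list(X.feature_names)
    for p in range(2, degree + 1):
        powered = X.values ** p
        block = standardize_columns(powered, [f"{n}^{p}" for n in X.feature_names])
        blocks.append(block.values)
        names.extend(block.feature_names)
    expanded = FeatureMatrix(np.hstack(blocks), names, standardized=True)
    groups = [[i + p * m for p in range(degree)] for i in range(m)]
    return expanded, ForbiddenSets.from_groups(expanded.m_cols, groups)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class CanonicalAutocorrelation(BaseEstimator):
    """Sparse within-matrix canonical correlation decomposition of one subject.

    Scikit-learn-style wrapper around :func:`fit_caa`: ``fit(X)`` standardizes
    the columns of a single subject's (n_timesteps, n_features) block and
    extracts up to ``max_pairs`` canonical pairs; ``transform(X)`` projects new
    rows onto the discovered axes, yielding ``(n, 2 * n_pairs_)`` scores
    ordered (Xu_0, Xv_0, Xu_1, ...).

    Parameters
    ----------
    c1, c2 : float
        L1 budgets of u and v; in [1, sqrt(n_features)], smaller is sparser.
    max_pairs : int
        Maximum number of deflation rounds.
    r2_min : float
        Retention filter on projection R^2 (strict inequality).
    tol, max_iter, n_restarts : optimizer controls.
    forbidden : ForbiddenSets, optional
        Grouped disjointness constraints; defaults to self-correlation only.
    random_state : int
        Seed for the restart coordinates.
    """

    def __init__(self, c1=1.75, c2=1.75, max_pairs=5, r2_min=0.25, tol=1e-6,
                 max_iter=500, n_restarts=4, forbidden=None, random_state=0):
        self.c1 = c1
        self.c2 = c2
        self.max_pairs = max_pairs
        self.r2_min = r2_min
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.forbidden = forbidden
        self.random_state = random_state

    def _config(self) -> SparsityConfig:
        return SparsityConfig(
            c1=self.c1, c2=self.c2, max_pairs=self.max_pairs, r2_min=self.r2_min,
            tol=self.tol, max_iter=self.max_iter, n_restarts=self.n_restarts,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        fm = standardize_columns(X)
        self.model_ = fit_caa(fm, self._config(), self.forbidden)
        self.pairs_ = self.model_.pairs
        self.n_pairs_ = len(self.pairs_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        if not self.pairs_:
            return np.empty((X.shape[0], 0))
        cols = []
        for p in self.pairs_:
            cols.append(Z @ p.u)
            cols.append(Z @ p.v)
        return np.column_stack(cols)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
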