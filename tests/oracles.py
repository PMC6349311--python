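"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the code paths they verify: the convex subproblem
is solved by a general-purpose NLP solver (SLSQP on the positive/negative
part splitting), neighbor votes by a naive scan over explicit distance
calls, and operating points by exhaustive threshold enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def kkt_subproblem_oracle(G: np.ndarray, v: np.ndarray, c: float,
                          blocked: np.ndarray) -> float:
    """Best objective u^T G v over ||u||2<=1, ||u||1<=c, u_i=0 on blocked,
    via SLSQP with u = p - q, p,q >= 0 (multi-start; returns the best)."""
    g = G @ v
    free = np.flatnonzero(~np.asarray(blocked))
    gf = g[free]
    mf = free.size
    if mf == 0:
        return 0.0

    def obj(z):
        return -gf @ (z[:mf] - z[mf:])

    def jac(z):
        return np.concatenate([-gf, gf])

    cons = [
        {"type": "ineq", "fun": lambda z: c - z.sum(),
         "jac": lambda z: -np.ones(2 * mf)},
        {"type": "ineq", "fun": lambda z: 1 - ((z[:mf] - z[mf:]) ** 2).sum(),
         "jac": lambda z: np.concatenate([-2 * (z[:mf] - z[mf:]),
                                          2 * (z[:mf] - z[mf:])])},
    ]
    u0 = gf / (np.linalg.norm(gf) + 1e-12)
    scale = min(1.0, c / (np.abs(u0).sum() + 1e-12))
    starts = [
        np.zeros(2 * mf),
        np.concatenate([np.maximum(u0 * scale, 0), np.maximum(-u0 * scale, 0)]),
    ]
    rng = np.random.default_rng(0)
    starts += [np.abs(rng.standard_normal(2 * mf)) * 0.1 for _ in range(2)]
    best = -np.inf
    for z0 in starts:
        res = minimize(obj, z0, jac=jac, method="SLSQP",
                       bounds=[(0, None)] * (2 * mf), constraints=cons,
                       options={"maxiter": 1000, "ftol": 1e-14})
        best = max(best, -res.fun)
    return float(best)


def naive_vote(query_pair, points, k: int, prune_radius: float,
               exclude_subject=None) -> tuple[float, int]:
    """Mean label of the k nearest labeled pairs by explicit scan."""
    from caekit.metric import canonical_distance

    rows = []
    for p in points:
        if exclude_subject is not None and p.subject_id == exclude_subject:
            continue
        rows.append((canonical_distance(query_pair, p.pair), p.subject_id,
                     p.pair.pair_index, p.label))
    rows = [r for r in rows if r[0] < prune_radius]
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    rows = rows[:k]
    if not rows:
        return 0.5, 0
    return float(np.mean([r[3] for r in rows])), len(rows)


def exhaustive_tpr_at_fpr(scores: np.ndarray, labels: np.ndarray,
                          target: float) -> float:
    """Maximum TPR with empirical FPR <= target over every possible strict
    threshold, by direct enumeration."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    best = 0.0
    for thr in np.concatenate([np.unique(scores), [scores.max()]]):
        pos = scores[labels == 1] > thr
        neg = scores[labels == 0] > thr
        if neg.mean() <= target:
            best = max(best, pos.mean())
    return float(best)
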