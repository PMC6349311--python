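"""Canonical autocorrelation embeddings (CAE).

A subject is represented by the set of its canonical pairs.  The distance
between two canonical spaces C1 = (u1, v1) and C2 = (u2, v2) is the chord
distance

    d(C1, C2) = min(||u1 - u2|| + ||v1 - v2||, ||u1 - v2|| + ||v1 - u2||)

additionally minimized over the joint sign flip of one argument: (-u, -v)
encodes the same correlation as (u, v), and the 4-element group
{identity, swap, flip, swap∘flip} acts by isometries, so the quotient
distance remains a metric on equivalence classes of correlation structures.
Neighbor queries are exact brute force with a pruning radius (default 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .caa import CAAModel, CanonicalPair

#: Every chord term is at most 2 for unit vectors, so distances are <= 4.
MAX_DISTANCE = 4.0


def canonical_distance(C1: CanonicalPair, C2: CanonicalPair) -> float:
    """Swap- and sign-minimized chord distance between two canonical spaces."""
    u1, v1 = C1.u, C1.v
    u2, v2 = C2.u, C2.v
    if u1.shape != u2.shape:
        raise ValueError(f"dimension mismatch: {u1.shape} vs {u2.shape}")
    variants = (
        np.linalg.norm(u1 - u2) + np.linalg.norm(v1 - v2),
        np.linalg.norm(u1 - v2) + np.linalg.norm(v1 - u2),
        np.linalg.norm(u1 + u2) + np.linalg.norm(v1 + v2),
        np.linalg.norm(u1 + v2) + np.linalg.norm(v1 + u2),
    )
    return float(min(variants))


def pairwise_distances(
    U1: np.ndarray, V1: np.ndarray, U2: np.ndarray, V2: np.ndarray
) -> np.ndarray:
    """Vectorized canonical distances between two stacks of unit pairs.

    Uses ||x - y||^2 = 2 - 2 x.y for unit vectors, so only four dot-product
    matrices are formed.
    """
    if U1.shape[1] != U2.shape[1]:
        raise ValueError("dimension mismatch between embeddings")

    def chord(dot: np.ndarray, sign: float) -> np.ndarray:
        return np.sqrt(np.maximum(2.0 + sign * 2.0 * dot, 0.0))

    uu, vv = U1 @ U2.T, V1 @ V2.T
    uv, vu = U1 @ V2.T, V1 @ U2.T
    stacked = np.stack([
        chord(uu, -1) + chord(vv, -1),
        chord(uv, -1) + chord(vu, -1),
        chord(uu, +1) + chord(vv, +1),
        chord(uv, +1) + chord(vu, +1),
    ])
    return stacked.min(axis=0)


@dataclass
class EmbeddingPoint:
    """One canonical pair placed in the embedding, with its subject and label."""

    pair: CanonicalPair
    subject_id: str
    label: int | None
    r_squared: float


@dataclass
class Embedding:
    """Labeled collection of canonical pairs with the chord metric attached.

    ``deferred_subjects`` records subjects that contributed zero retained
    pairs — they are never silently dropped, and downstream classification
    defers on them.
    """

    points: list[EmbeddingPoint]
    prune_radius: float = 2.0
    metric_version: str = "chord-swap-sign-v1"
    deferred_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.prune_radius <= 0:
            raise ValueError("prune_radius must be positive")
        dims = {p.pair.u.shape[0] for p in self.points}
        if len(dims) > 1:
            raise ValueError(f"mixed vector dimensions in embedding: {sorted(dims)}")
        self._refresh_arrays()

    def _refresh_arrays(self) -> None:
        if self.points:
            self.U = np.vstack([p.pair.u for p in self.points])
            self.V = np.vstack([p.pair.v for p in self.points])
        else:
            self.U = np.empty((0, 0))
            self.V = np.empty((0, 0))
        self.labels = np.array(
            [-1 if p.label is None else int(p.label) for p in self.points], dtype=int
        )
        self.subject_ids = [p.subject_id for p in self.points]

    def __len__(self) -> int:
        return len(self.points)

    def distances_to(self, query: CanonicalPair) -> np.ndarray:
        if not self.points:
            return np.empty(0)
        q = query.u[None, :]
        return pairwise_distances(q, query.v[None, :], self.U, self.V)[0]


def build_embedding(
    models: Sequence[CAAModel],
    labels: Sequence[int | None] | None = None,
    r2_min: float = 0.25,
    prune_radius: float = 2.0,
) -> Embedding:
    """Assemble per-subject canonical pairs into one embedded point set.

    Admits only pairs with ``r_squared > r2_min`` (strict, matching the
    retention filter); subjects left with zero admitted pairs go to the
    deferral list.
    """
    if labels is None:
        labels = [None] * len(models)
    if len(labels) != len(models):
        raise ValueError("labels length must match models")
    points: list[EmbeddingPoint] = []
    deferred: list[str] = []
    for model, label in zip(models, labels):
        sid = model.subject_id if model.subject_id is not None else "?"
        admitted = [p for p in model.pairs if p.r_squared > r2_min]
        if not admitted:
            deferred.append(sid)
            continue
        for p in admitted:
            points.append(EmbeddingPoint(pair=p, subject_id=sid, label=label,
                                         r_squared=p.r_squared))
    return Embedding(points=points, prune_radius=prune_radius,
                     deferred_subjects=deferred)


def neighbors_within(
    embedding: Embedding, query: CanonicalPair, k: int
) -> list[tuple[EmbeddingPoint, float]]:
    """Up to k nearest points closer than the pruning radius, ascending by
    distance with deterministic (subject_id, pair_index) tie-breaking.  May
    return fewer than k points, including none."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not embedding.points:
        return []
    dist = embedding.distances_to(query)
    keep = np.flatnonzero(dist < embedding.prune_radius)
    ranked = sorted(
        keep,
        key=lambda i: (dist[i], embedding.subject_ids[i], embedding.points[i].pair.pair_index),
    )
    return [(embedding.points[i], float(dist[i])) for i in ranked[:k]]
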