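"""Delimited-text and JSON interchange for models, embeddings and cohorts."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .caa import CAAModel, CanonicalPair, ForbiddenSets, SparsityConfig
from .metric import Embedding, EmbeddingPoint


def read_subject_csv(path, epoch_rows: tuple[int, int] | None = None):
    """Read one subject's matrix (header row of feature names, one row per
    timestamp); ``epoch_rows=(start, end)`` selects the half-open row range."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface file context for the CLI
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if epoch_rows is not None:
        start, end = epoch_rows
        df = df.iloc[start:end]
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = int(np.argwhere(~np.isfinite(values))[0][0])
        raise ValueError(f"non-finite value in {path} near data row {bad}")
    return values, list(df.columns)


def read_labels_csv(path) -> dict[str, int]:
    df = pd.read_csv(path)
    if not {"subject_id", "label"} <= set(df.columns):
        raise ValueError(f"{path} must have subject_id,label columns")
    return {str(r.subject_id): int(r.label) for r in df.itertuples()}


def _sparse(vec: np.ndarray) -> dict[str, float]:
    return {str(i): float(vec[i]) for i in np.flatnonzero(vec)}


def _dense(sparse: dict, m: int) -> np.ndarray:
    out = np.zeros(m)
    for i, val in sparse.items():
        out[int(i)] = float(val)
    return out


def pair_to_dict(pair: CanonicalPair, m: int) -> dict:
    return {
        "u": _sparse(pair.u),
        "v": _sparse(pair.v),
        "d": pair.d,
        "r_squared": pair.r_squared,
        "subject_id": pair.subject_id,
        "pair_index": pair.pair_index,
        "iterations": pair.iterations,
        "restart_index": pair.restart_index,
        "converged": pair.converged,
        "m": m,
    }


def pair_from_dict(d: dict) -> CanonicalPair:
    m = int(d["m"])
    return CanonicalPair(
        u=_dense(d["u"], m), v=_dense(d["v"], m), d=float(d["d"]),
        r_squared=float(d["r_squared"]), subject_id=d.get("subject_id"),
        pair_index=int(d.get("pair_index", 0)),
        iterations=int(d.get("iterations", 0)),
        restart_index=int(d.get("restart_index", 0)),
        converged=bool(d.get("converged", True)),
    )


def model_to_dict(model: CAAModel) -> dict:
    m = model.forbidden.m
    return {
        "subject_id": model.subject_id,
        "feature_names": model.feature_names,
        "config": asdict(model.config),
        "pairs": [pair_to_dict(p, m) for p in model.pairs],
        "objective_trace": model.objective_trace,
        "m": m,
    }


def model_from_dict(d: dict) -> CAAModel:
    m = int(d["m"])
    return CAAModel(
        pairs=[pair_from_dict(p) for p in d["pairs"]],
        config=SparsityConfig(**d["config"]),
        forbidden=ForbiddenSets.default(m),
        objective_trace=[list(t) for t in d.get("objective_trace", [])],
        feature_names=list(d.get("feature_names", [])),
        subject_id=d.get("subject_id"),
    )


def save_model(model: CAAModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))


def load_model(path) -> CAAModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def embedding_to_dict(e: Embedding) -> dict:
    m = e.U.shape[1] if len(e) else 0
    return {
        "prune_radius": e.prune_radius,
        "metric_version": e.metric_version,
        "deferred_subjects": e.deferred_subjects,
        "m": m,
        "points": [
            {
                "pair": pair_to_dict(p.pair, m),
                "subject_id": p.subject_id,
                "label": p.label,
                "r_squared": p.r_squared,
            }
            for p in e.points
        ],
    }


def embedding_from_dict(d: dict, validate: bool = True) -> Embedding:
    points = []
    for pd_ in d["points"]:
        pair = pair_from_dict(pd_["pair"])
        if validate:
            for name, vec in (("u", pair.u), ("v", pair.v)):
                if abs(np.linalg.norm(vec) - 1.0) > 1e-6:
                    raise ValueError(
                        f"invalid embedding: ||{name}||_2 != 1 for subject "
                        f"{pd_['subject_id']} pair {pair.pair_index}"
                    )
        label = pd_.get("label")
        points.append(EmbeddingPoint(
            pair=pair, subject_id=pd_["subject_id"],
            label=None if label is None else int(label),
            r_squared=float(pd_["r_squared"]),
        ))
    return Embedding(points=points, prune_radius=float(d.get("prune_radius", 2.0)),
                     metric_version=d.get("metric_version", "chord-swap-sign-v1"),
                     deferred_subjects=list(d.get("deferred_subjects", [])))


def save_embedding(e: Embedding, path) -> None:
    Path(path).write_text(json.dumps(embedding_to_dict(e), indent=1, sort_keys=True))


def load_embedding(path, validate: bool = True) -> Embedding:
    return embedding_from_dict(json.loads(Path(path).read_text()), validate=validate)


def distance_matrix_csv(e: Embedding, path) -> None:
    """Pairwise canonical distances between embedded points, for external
    clustering tools."""
    from .metric import pairwise_distances

    ids = [f"{p.subject_id}:{p.pair.pair_index}" for p in e.points]
    D = pairwise_distances(e.U, e.V, e.U, e.V)
    pd.DataFrame(D, index=ids, columns=ids).to_csv(path)
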