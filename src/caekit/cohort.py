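"""Synthetic monitored-patient cohorts with planted sparse correlation structures.

The generator emulates the statistical object CAA consumes — a per-subject
matrix of 1 Hz summary features over a two-hour epoch (default 7200 x 66)
with sparse latent cross-feature correlations — not the clinical meaning of
any real qEEG feature.  A cohort of 80 subjects split into two balanced
outcome classes carries one correlation structure shared by everyone plus
one class-discriminative structure, mirroring the premise that some
correlation patterns are common while others separate outcomes.

Each planted structure draws the two feature blocks from a zero-mean
Gaussian with covariance

    [[I, r * w_a w_b^T], [r * w_b w_a^T, I]],   r = sqrt(target_r2),

so every feature has exactly unit marginal variance (no class-separating
marginals), features are uncorrelated *within* each block, and the
population canonical correlation between the blocks is exactly r with
canonical weights w_a, w_b.  The planted partition is therefore the unique
argmax of the CAA objective, and no noise-variance calibration is needed —
the population R^2 equals target_r2 in closed form.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .caa import FeatureMatrix


@dataclass
class StructureSpec:
    """One planted correlation structure between two disjoint feature blocks."""

    support_a: tuple[int, ...]
    support_b: tuple[int, ...]
    target_r2: float = 0.8
    weights_a: tuple[float, ...] | None = None  # None -> uniform
    weights_b: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.support_a = tuple(int(i) for i in self.support_a)
        self.support_b = tuple(int(i) for i in self.support_b)
        if set(self.support_a) & set(self.support_b):
            raise ValueError("structure blocks must be disjoint")
        if not self.support_a or not self.support_b:
            raise ValueError("structure blocks must be nonempty")
        if not 0.0 < self.target_r2 < 1.0:
            raise ValueError("target_r2 must lie in (0, 1)")

    def unit_weights(self) -> tuple[np.ndarray, np.ndarray]:
        wa = np.asarray(self.weights_a if self.weights_a is not None
                        else np.ones(len(self.support_a)), dtype=float)
        wb = np.asarray(self.weights_b if self.weights_b is not None
                        else np.ones(len(self.support_b)), dtype=float)
        return wa / np.linalg.norm(wa), wb / np.linalg.norm(wb)


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the monitored-cohort shape: 40 subjects per outcome
    class, 66 features at 1 Hz over a two-hour epoch (7200 rows).  The
    default structures plant one shared and one class-1-only correlation at
    R^2 = 0.8.  ``ar_coeff`` optionally colors the noise with an AR(1)
    process (default off: rows are exchangeable within the epoch, as the
    method assumes).  ``mean_shift_delta``/``mean_shift_features`` add a
    class-1 mean offset (in units of the feature SD) for experiments where
    the signal lives in the marginals instead of the correlations.
    """

    n_subjects_per_class: int = 40
    n_features: int = 66
    n_timesteps: int = 7200
    shared_structures: list[StructureSpec] = field(
        default_factory=lambda: [StructureSpec((0, 1, 2), (3, 4, 5), 0.8)])
    class0_structures: list[StructureSpec] = field(default_factory=list)
    class1_structures: list[StructureSpec] = field(
        default_factory=lambda: [StructureSpec((6, 7, 8), (9, 10, 11), 0.8)])
    noise_sd: float = 1.0
    ar_coeff: float = 0.0
    mean_shift_delta: float = 0.0
    mean_shift_features: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timesteps < 2:
            raise ValueError("n_timesteps must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        for s in self.all_structures():
            top = max(max(s.support_a), max(s.support_b))
            if top >= self.n_features:
                raise ValueError("structure support outside feature range")

    def all_structures(self) -> list[StructureSpec]:
        return list(self.shared_structures) + list(self.class0_structures) \
            + list(self.class1_structures)

    def structures_for(self, class_label: int) -> list[StructureSpec]:
        extra = self.class1_structures if class_label == 1 else self.class0_structures
        return list(self.shared_structures) + list(extra)


def _check_disjoint(structures: list[StructureSpec]) -> None:
    seen: set[int] = set()
    for s in structures:
        block = set(s.support_a) | set(s.support_b)
        if seen & block:
            raise ValueError("overlapping supports across simultaneously active structures")
        seen |= block


def generate_subject(
    cfg: CohortConfig, class_label: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[float]]:
    """One raw (unstandardized) subject matrix plus the realized empirical R^2
    of each active planted structure."""
    structures = cfg.structures_for(class_label)
    _check_disjoint(structures)
    n, m = cfg.n_timesteps, cfg.n_features
    M = rng.standard_normal((n, m))
    if cfg.ar_coeff > 0:
        phi = cfg.ar_coeff
        for t in range(1, n):
            M[t] = phi * M[t - 1] + np.sqrt(1 - phi * phi) * M[t]
    realized: list[float] = []
    for s in structures:
        wa, wb = s.unit_weights()
        r = float(np.sqrt(s.target_r2))
        a = M[:, s.support_a]            # iid N(0, I): block A as drawn
        fa = a @ wa                      # canonical variate of block A
        xi = M[:, s.support_b]
        # b = r*wb*fa + (I - (1 - sqrt(1-r^2)) wb wb^T) xi  ->  cov(b) = I
        shrink = 1.0 - np.sqrt(1.0 - r * r)
        b = np.outer(fa, r * wb) + xi - shrink * np.outer(xi @ wb, wb)
        M[:, s.support_b] = b
        rho = float(np.corrcoef(fa, b @ wb)[0, 1])
        realized.append(rho * rho)
    M *= cfg.noise_sd
    if class_label == 1 and cfg.mean_shift_delta and cfg.mean_shift_features:
        M[:, list(cfg.mean_shift_features)] += cfg.mean_shift_delta * cfg.noise_sd
    return M, realized


def generate_cohort(cfg: CohortConfig):
    """Balanced two-class cohort plus a ground-truth manifest.

    Returns ``(subjects, manifest)`` where subjects is a list of
    ``(subject_id, raw_matrix, label)`` and the manifest echoes the config and
    records, per subject, the active structures and their realized empirical
    R^2.  Regeneration from ``cfg.seed`` is bit-identical.
    """
    n_total = 2 * cfg.n_subjects_per_class
    children = np.random.SeedSequence(cfg.seed).spawn(n_total)
    subjects = []
    manifest_subjects = []
    for i in range(n_total):
        label = 0 if i < cfg.n_subjects_per_class else 1
        sid = f"s{i:03d}"
        rng = np.random.default_rng(children[i])
        M, realized = generate_subject(cfg, label, rng)
        subjects.append((sid, M, label))
        manifest_subjects.append({
            "subject_id": sid,
            "label": label,
            "spawn_key": list(children[i].spawn_key),
            "structures": [
                {
                    "support_a": list(s.support_a),
                    "support_b": list(s.support_b),
                    "target_r2": s.target_r2,
                    "realized_r2": realized[j],
                }
                for j, s in enumerate(cfg.structures_for(label))
            ],
        })
    manifest = {"config": config_to_dict(cfg), "subjects": manifest_subjects}
    return subjects, manifest


def config_to_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["mean_shift_features"] = list(cfg.mean_shift_features)
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    for key in ("shared_structures", "class0_structures", "class1_structures"):
        d[key] = [StructureSpec(**s) for s in d.get(key, [])]
    d["mean_shift_features"] = tuple(d.get("mean_shift_features", ()))
    return CohortConfig(**d)


def feature_names(cfg: CohortConfig) -> list[str]:
    return [f"f{i:03d}" for i in range(cfg.n_features)]


def to_feature_matrix(raw: np.ndarray, cfg: CohortConfig) -> FeatureMatrix:
    return FeatureMatrix(raw, feature_names(cfg), standardized=False)


def write_fixtures(subjects, manifest, directory) -> list[Path]:
    """One CSV per subject, a labels CSV, and the manifest JSON.

    Floats round-trip exactly (shortest-repr formatting).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    m = subjects[0][1].shape[1]
    names = [f"f{i:03d}" for i in range(m)]
    written = []
    for sid, M, _label in subjects:
        path = directory / f"{sid}.csv"
        pd.DataFrame(M, columns=names).to_csv(path, index=False)
        written.append(path)
    labels_path = directory / "labels.csv"
    pd.DataFrame(
        {"subject_id": [s[0] for s in subjects], "label": [s[2] for s in subjects]}
    ).to_csv(labels_path, index=False)
    written.append(labels_path)
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written.append(manifest_path)
    return written
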