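import numpy as np
import pytest

from caekit.caa import SparsityConfig, fit_caa
from caekit.cohort import CohortConfig, StructureSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """16 subjects, 12 features, 1500 timesteps: one shared + one class-1
    structure at R^2 = 0.8 — a desk-scale version of the default study."""
    cfg = CohortConfig(
        n_subjects_per_class=8, n_features=12, n_timesteps=1500,
        shared_structures=[StructureSpec((0, 1), (2, 3), 0.8)],
        class1_structures=[StructureSpec((6, 7), (8, 9), 0.8)],
        seed=123,
    )
    subjects, manifest = generate_cohort(cfg)
    return cfg, subjects, manifest


@pytest.fixture(scope="session")
def small_cohort_models(small_cohort):
    cfg, subjects, _ = small_cohort
    models = [fit_caa(M, SparsityConfig(c1=1.5, c2=1.5, seed=5 + i), subject_id=sid)
              for i, (sid, M, _) in enumerate(subjects)]
    labels = {sid: lab for sid, _, lab in subjects}
    return models, labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_correlation_gram(rng, m: int) -> np.ndarray:
    """Random PSD matrix with unit diagonal (a valid gram of standardized data)."""
    A = rng.standard_normal((m + 3, m))
    G = A.T @ A / (m + 3)
    d = np.sqrt(np.diag(G))
    return G / np.outer(d, d)
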