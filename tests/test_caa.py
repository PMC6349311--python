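"""Unit and property tests for the sparse autocorrelation solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from caekit.caa import (
    CanonicalAutocorrelation,
    DegenerateStepError,
    ForbiddenSets,
    NoStructureError,
    SparsityConfig,
    alternate_convex_search,
    canonicalize_sign,
    compute_lambda1,
    compute_r_squared,
    deflate_gram,
    expand_polynomial_features,
    fit_caa,
    kkt_solve_step,
    soft_threshold_weighted,
    standardize_columns,
)
from caekit.cohort import CohortConfig, StructureSpec, generate_subject
from conftest import random_correlation_gram
from oracles import kkt_subproblem_oracle


class TestStandardize:
    def test_three_point_column(self):
        fm = standardize_columns(np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]))
        np.testing.assert_allclose(fm.values[:, 0], [-1.0, 0.0, 1.0])
        # proportional columns standardize identically (scale invariance)
        np.testing.assert_allclose(fm.values[:, 0], fm.values[:, 1])
        assert fm.standardized

    def test_large_gaussian_block(self, rng):
        fm = standardize_columns(rng.standard_normal((1000, 5)))
        assert np.all(np.abs(fm.values.mean(axis=0)) < 1e-10)
        assert np.allclose(fm.values.std(axis=0, ddof=1), 1.0)

    def test_constant_column_is_named_in_error(self):
        M = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match="f001"):
            standardize_columns(M)


class TestLambda1:
    def test_direct_formula(self):
        fb = ForbiddenSets.default(2)
        g = np.array([2.0, 3.0])
        assert compute_lambda1(g, np.array([1.0, 0.5]), fb) == pytest.approx(6.0)
        assert compute_lambda1(g, np.array([1.0, 0.0]), fb) == pytest.approx(2.0)

    def test_zero_v_rejected(self):
        with pytest.raises(ValueError):
            compute_lambda1(np.ones(3), np.zeros(3), ForbiddenSets.default(3))

    def test_threshold_zeroes_exactly_forbidden_support(self, rng):
        m = 6
        fb = ForbiddenSets.default(m)
        for _ in range(20):
            g = rng.standard_normal(m)
            v = rng.standard_normal(m) * (rng.random(m) < 0.6)
            if not np.any(v):
                continue
            lam1 = compute_lambda1(g, v, fb)
            w = fb.weights(v)
            s = soft_threshold_weighted(g, lam1 * w)
            # forbidden support zeroed (up to the rounding of lam1 * w);
            # zero-weight coordinates pass through untouched
            assert np.all(np.abs(s[w > 0]) < 1e-12)
            assert np.all(s[w == 0] == g[w == 0])
            # any smaller multiplier leaves some forbidden coordinate alive
            s_low = soft_threshold_weighted(g, 0.99 * lam1 * w)
            assert np.any(np.abs(s_low[w > 0]) > 0)


@given(
    g=hnp.arrays(np.float64, 5, elements=st.floats(-10, 10)),
    theta=hnp.arrays(np.float64, 5, elements=st.floats(0, 10)),
)
@settings(max_examples=50, deadline=None)
def test_soft_threshold_definition(g, theta):
    out = soft_threshold_weighted(g, theta)
    np.testing.assert_allclose(out, np.sign(g) * np.maximum(np.abs(g) - theta, 0))
    # identity at zero threshold, shrinkage otherwise
    np.testing.assert_allclose(soft_threshold_weighted(g, 0.0), g)
    assert np.all(np.abs(out) <= np.abs(g) + 1e-15)


def test_soft_threshold_worked_values():
    np.testing.assert_allclose(
        soft_threshold_weighted(np.array([3.0, -0.5]), np.array([1.0, 1.0])),
        [2.0, 0.0],
    )
    np.testing.assert_allclose(
        soft_threshold_weighted(np.array([1.0, -2.0, 3.0]), np.array([0.5, 0.5, 10.0])),
        [0.5, -1.5, 0.0],
    )


class TestKKTStep:
    def test_hand_example_slack_l1(self):
        G = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        u, params = kkt_solve_step(G, np.array([1.0, 0, 0]), 1.2, ForbiddenSets.default(3))
        np.testing.assert_allclose(u, np.array([0, 0.9, 0.1]) / np.hypot(0.9, 0.1),
                                   atol=1e-12)
        assert params.lambda1 == pytest.approx(1.0)
        assert params.lambda2 == 0.0

    def test_two_features_forces_other_axis(self, rng):
        G = random_correlation_gram(rng, 2)
        u, _ = kkt_solve_step(G, np.array([1.0, 0.0]), np.sqrt(2), ForbiddenSets.default(2))
        np.testing.assert_allclose(np.abs(u), [0.0, 1.0], atol=1e-12)

    def test_degenerate_when_everything_blocked(self):
        G = np.eye(2)
        with pytest.raises(DegenerateStepError):
            kkt_solve_step(G, np.array([1.0, 0.0]), 1.0, ForbiddenSets.default(2))

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_numerical_solver(self, trial):
        rng = np.random.default_rng(900 + trial)
        m = int(rng.integers(3, 9))
        G = random_correlation_gram(rng, m)
        fb = ForbiddenSets.default(m)
        k = int(rng.integers(1, max(2, m // 2)))
        v = np.zeros(m)
        supp = rng.choice(m, k, replace=False)
        v[supp] = rng.standard_normal(k)
        v /= np.linalg.norm(v)
        c = float(rng.uniform(1, np.sqrt(m)))
        try:
            u, params = kkt_solve_step(G, v, c, fb)
        except DegenerateStepError:
            return
        assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-8)
        assert np.abs(u).sum() <= c * (1 + 1e-8)
        if params.lambda2 > 0:
            assert np.abs(u).sum() == pytest.approx(c, abs=1e-6)
        ours = float(u @ G @ v)
        ref = kkt_subproblem_oracle(G, v, c, fb.weights(v) > 0)
        assert ours == pytest.approx(ref, abs=1e-6)


class TestAlternateSearch:
    def test_recovers_planted_blocks(self):
        cfg = CohortConfig(n_features=10, n_timesteps=3000,
                           shared_structures=[StructureSpec((0, 1, 2), (3, 4, 5), 0.9)],
                           class1_structures=[])
        M, _ = generate_subject(cfg, 0, np.random.default_rng(7))
        fm = standardize_columns(M)
        G = fm.values.T @ fm.values / (fm.n_rows - 1)
        pair = alternate_convex_search(G, SparsityConfig(seed=7))
        supports = {frozenset(pair.support("u", 0.1)), frozenset(pair.support("v", 0.1))}
        assert supports == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_no_correlation_gives_small_d(self, rng):
        # empirical gram of pure noise: best sparse correlation is tiny
        X = standardize_columns(rng.standard_normal((4000, 8)))
        G = X.values.T @ X.values / (X.n_rows - 1)
        pair = alternate_convex_search(G, SparsityConfig(seed=0))
        assert pair.d < 0.3

    def test_ascent_and_sign_canonicalization(self, rng):
        G = random_correlation_gram(rng, 8)
        pair = alternate_convex_search(G, SparsityConfig(seed=3))
        trace = np.array(pair.objective_trace)
        assert np.all(np.diff(trace) >= -1e-10)
        i = int(np.argmax(np.abs(pair.u)))
        assert pair.u[i] > 0
        assert pair.d >= 0

    def test_swapped_init_gives_same_structure(self):
        from caekit.metric import canonical_distance

        cfg = CohortConfig(n_features=8, n_timesteps=4000,
                           shared_structures=[StructureSpec((0, 1), (2, 3), 0.9)],
                           class1_structures=[])
        M, _ = generate_subject(cfg, 0, np.random.default_rng(21))
        fm = standardize_columns(M)
        G = fm.values.T @ fm.values / (fm.n_rows - 1)
        sc = SparsityConfig(c1=1.4, c2=1.4)
        e0, e2 = np.zeros(8), np.zeros(8)
        e0[0] = 1.0
        e2[2] = 1.0
        p_a = alternate_convex_search(G, sc, v_init=e0)
        p_b = alternate_convex_search(G, sc, v_init=e2)
        assert canonical_distance(p_a, p_b) < 1e-3


def test_canonicalize_sign_flips_jointly():
    u = np.array([0.1, -0.9])
    v = np.array([0.5, 0.5])
    cu, cv = canonicalize_sign(u, v)
    np.testing.assert_allclose(cu, -u)
    np.testing.assert_allclose(cv, -v)


class TestRSquaredAndDeflation:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        M = np.column_stack([x, 2 * x, rng.standard_normal(500)])
        fm = standardize_columns(M)
        from caekit.caa import CanonicalPair

        pair = CanonicalPair(u=np.array([1.0, 0, 0]), v=np.array([0, 1.0, 0]), d=1.0)
        assert compute_r_squared(fm, pair) == pytest.approx(1.0, abs=1e-10)

    def test_independent_noise_r2_small(self, rng):
        fm = standardize_columns(rng.standard_normal((7200, 4)))
        from caekit.caa import CanonicalPair

        pair = CanonicalPair(u=np.array([1.0, 0, 0, 0]), v=np.array([0, 1.0, 0, 0]), d=0.0)
        assert compute_r_squared(fm, pair) < 0.01

    def test_deflation_direct_algebra(self):
        from caekit.caa import CanonicalPair

        G = np.eye(3)
        G[0, 1] = G[1, 0] = 0.9
        pair = CanonicalPair(u=np.array([1.0, 0, 0]), v=np.array([0, 1.0, 0]), d=0.9)
        G2 = deflate_gram(G, pair)
        assert G2[0, 1] == pytest.approx(0.0)
        assert G2[1, 0] == pytest.approx(0.0)
        np.testing.assert_allclose(G2, G2.T)
        assert abs(pair.u @ G2 @ pair.v) < 1e-8

    def test_refit_after_deflation_moves_away(self, rng):
        from caekit.metric import canonical_distance

        hits = 0
        for trial in range(20):
            local = np.random.default_rng(3000 + trial)
            G = random_correlation_gram(local, 7)
            cfg = SparsityConfig(seed=trial)
            try:
                p1 = alternate_convex_search(G, cfg)
                p2 = alternate_convex_search(deflate_gram(G, p1), cfg)
            except NoStructureError:
                continue
            assert canonical_distance(p1, p2) > 1e-3
            hits += 1
        assert hits > 10


class TestFitCAA:
    def test_two_structures_recovered_in_strength_order(self):
        cfg = CohortConfig(
            n_features=14, n_timesteps=4000,
            shared_structures=[StructureSpec((0, 1, 2), (3, 4, 5), 0.9),
                               StructureSpec((6, 7, 8), (9, 10, 11), 0.75)],
            class1_structures=[])
        M, _ = generate_subject(cfg, 0, np.random.default_rng(5))
        model = fit_caa(M, SparsityConfig(seed=5))
        assert model.n_pairs == 2
        first = model.pairs[0].support("u", 0.1) | model.pairs[0].support("v", 0.1)
        second = model.pairs[1].support("u", 0.1) | model.pairs[1].support("v", 0.1)
        assert first == {0, 1, 2, 3, 4, 5}          # stronger structure first
        assert second == {6, 7, 8, 9, 10, 11}
        assert model.pairs[0].d > model.pairs[1].d
        # max_pairs=1 keeps only the stronger one
        m1 = fit_caa(M, SparsityConfig(max_pairs=1, seed=5))
        assert m1.n_pairs == 1
        assert m1.pairs[0].support("u", 0.1) | m1.pairs[0].support("v", 0.1) == first

    def test_pure_noise_retains_nothing(self, rng):
        M = rng.standard_normal((7200, 10))
        model = fit_caa(M, SparsityConfig(seed=1))
        assert model.n_pairs == 0

    def test_retained_pairs_respect_filter_and_invariants(self, small_cohort_models):
        models, _ = small_cohort_models
        assert any(m.n_pairs for m in models)
        for model in models:
            for pair in model.pairs:
                assert pair.r_squared > model.config.r2_min
                pair.validate(model.config.c1, model.config.c2, model.forbidden)

    def test_prefers_correlation_over_dominant_variance(self):
        # high-variance isotropic features must not attract the leading pair
        rng = np.random.default_rng(17)
        n = 4000
        cfg = CohortConfig(n_features=10, n_timesteps=n,
                           shared_structures=[StructureSpec((4, 5), (6, 7), 0.85)],
                           class1_structures=[])
        M, _ = generate_subject(cfg, 0, rng)
        M[:, :4] *= 50.0  # dominant variance, zero cross-correlation
        model = fit_caa(M, SparsityConfig(c1=1.4, c2=1.4, seed=17, max_pairs=1))
        assert model.n_pairs == 1
        occupied = model.pairs[0].support("u", 0.1) | model.pairs[0].support("v", 0.1)
        assert occupied == {4, 5, 6, 7}


class TestPolynomialExpansion:
    def test_construction_rule(self, rng):
        fm = standardize_columns(rng.standard_normal((100, 2)))
        ex, fb = expand_polynomial_features(fm, degree=2)
        assert ex.m_cols == 4
        assert ex.feature_names == ["f000", "f001", "f000^2", "f001^2"]
        sets = fb.sets()
        assert sets[0] == {0, 2}
        assert sets[1] == {1, 3}

    def test_quadratic_relation_found(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(4000)
        y = x ** 2 + 0.05 * rng.standard_normal(4000)
        M = np.column_stack([x, y, rng.standard_normal(4000)])
        fm = standardize_columns(M)
        ex, fb = expand_polynomial_features(fm, degree=2)
        model = fit_caa(ex, SparsityConfig(c1=1.0, c2=1.0, seed=2), fb)
        assert model.n_pairs >= 1
        top = model.pairs[0]
        assert top.r_squared > 0.9
        occupied = top.support("u") | top.support("v")
        assert occupied == {1, 3}  # y matched with x^2 (column index 3)

    def test_no_pair_straddles_a_forbidden_group(self, rng):
        for trial in range(5):
            local = np.random.default_rng(4000 + trial)
            M = local.standard_normal((500, 4))
            fm = standardize_columns(M)
            ex, fb = expand_polynomial_features(fm, degree=2)
            model = fit_caa(ex, SparsityConfig(c1=1.2, c2=1.2, r2_min=0.0, seed=trial), fb)
            for pair in model.pairs:
                assert fb.violation(pair.u, pair.v) == 0.0


class TestEstimator:
    def test_sklearn_conventions(self, small_cohort):
        from sklearn.base import clone

        _, subjects, _ = small_cohort
        est = CanonicalAutocorrelation(c1=1.5, c2=1.5, random_state=0)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.fit(subjects[0][1])
        assert est.n_pairs_ >= 1
        scores = est.transform(subjects[0][1])
        assert scores.shape == (subjects[0][1].shape[0], 2 * est.n_pairs_)
        # projection scores of a retained pair are strongly correlated
        r = np.corrcoef(scores[:, 0], scores[:, 1])[0, 1]
        assert r ** 2 > 0.25

    def test_infeasible_budget_rejected(self, rng):
        with pytest.raises(ValueError, match="c1"):
            CanonicalAutocorrelation(c1=0.5).fit(rng.standard_normal((50, 4)))
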