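"""Shapley attribution: axioms, estimator agreement, tree-path correctness."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fncxplain.shapley import (EnumerationLimitError, exact_shapley,
                               interaction_value, sampling_shapley, tree_shapley)
from fncxplain.trees import TreeEnsemble, fit_cart, fit_gbm

from conftest import brute_force_tree_shapley, random_tree


class TestExactShapley:
    def test_additive_model_recovers_coefficients(self):
        f = lambda Z: Z[:, 0] + 2 * Z[:, 1]
        av = exact_shapley(f, np.array([3.0, 4.0]), np.zeros((1, 2)))
        assert av.phi == pytest.approx([3.0, 8.0])
        assert av.base_value == pytest.approx(0.0)

    def test_dummy_feature_gets_zero(self, rng):
        f = lambda Z: Z[:, 0] ** 2
        av = exact_shapley(f, rng.normal(size=3), rng.normal(size=(10, 3)))
        assert av.phi[1] == pytest.approx(0.0, abs=1e-12)
        assert av.phi[2] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_features_share_attribution(self, rng):
        f = lambda Z: Z[:, 0] * Z[:, 1] + Z[:, 0] + Z[:, 1]
        x = np.array([1.5, 1.5, -0.3])
        bg = rng.normal(size=(8, 3))
        bg[:, 1] = bg[:, 0]  # identical marginals for the symmetric pair
        av = exact_shapley(f, x, bg)
        assert av.phi[0] == pytest.approx(av.phi[1], abs=1e-12)

    def test_efficiency_on_random_nonlinear_models(self, rng):
        for _ in range(10):
            W = rng.normal(size=(4, 4))
            f = lambda Z: np.tanh(Z @ W).sum(axis=1)
            x = rng.normal(size=4)
            bg = rng.normal(size=(6, 4))
            av = exact_shapley(f, x, bg)
            assert av.total == pytest.approx(float(f(x[None])[0]), abs=1e-10)

    def test_linearity_of_the_attribution_operator(self, rng):
        f1 = lambda Z: Z[:, 0] * Z[:, 1]
        f2 = lambda Z: np.abs(Z[:, 1]) + Z[:, 0]
        both = lambda Z: f1(Z) + 2.0 * f2(Z)
        x = rng.normal(size=2)
        bg = rng.normal(size=(7, 2))
        a1 = exact_shapley(f1, x, bg)
        a2 = exact_shapley(f2, x, bg)
        ab = exact_shapley(both, x, bg)
        assert ab.phi == pytest.approx(a1.phi + 2.0 * a2.phi, abs=1e-12)

    def test_background_swap_moves_base_but_keeps_efficiency(self, rng):
        f = lambda Z: Z[:, 0] * Z[:, 1] + Z[:, 1]
        x = rng.normal(size=2)
        a1 = exact_shapley(f, x, rng.normal(size=(5, 2)))
        a2 = exact_shapley(f, x, 3.0 + rng.normal(size=(5, 2)))
        assert a1.base_value != pytest.approx(a2.base_value)
        assert a1.total == pytest.approx(a2.total, abs=1e-10)

    def test_enumeration_limit_directs_to_sampling(self, rng):
        f = lambda Z: Z.sum(axis=1)
        with pytest.raises(EnumerationLimitError, match="sampling_shapley"):
            exact_shapley(f, np.zeros(20), np.zeros((1, 20)))


class TestSamplingShapley:
    def test_agrees_with_exact_within_monte_carlo_error(self, rng):
        W = rng.normal(size=6)
        f = lambda Z: Z @ W + 0.5 * Z[:, 0] * Z[:, 1]
        x = rng.normal(size=6)
        bg = rng.normal(size=(15, 6))
        ex = exact_shapley(f, x, bg)
        sa = sampling_shapley(f, x, bg, n_permutations=400, seed=2)
        z = np.abs(sa.phi - ex.phi) / np.maximum(sa.stderr, 1e-12)
        assert np.all(z < 3.0)

    def test_standard_error_shrinks_like_root_n(self):
        rng = np.random.default_rng(0)
        f = lambda Z: Z[:, 0] * Z[:, 1] + Z[:, 2]
        x = np.array([1.0, -2.0, 0.5])
        bg = rng.normal(size=(10, 3))
        se_n = sampling_shapley(f, x, bg, n_permutations=100, seed=3).stderr
        se_4n = sampling_shapley(f, x, bg, n_permutations=400, seed=3).stderr
        ratio = se_n[se_n > 0] / se_4n[se_n > 0]
        assert np.median(ratio) == pytest.approx(2.0, rel=0.35)

    def test_all_permutations_reproduce_exact_values(self, rng):
        f = lambda Z: Z[:, 0] * Z[:, 1] + np.abs(Z[:, 2])
        x = np.array([1.0, 2.0, -3.0])
        bg = rng.normal(size=(9, 3))
        ex = exact_shapley(f, x, bg)
        sa = sampling_shapley(f, x, bg, permutations=list(itertools.permutations(range(3))))
        assert sa.phi == pytest.approx(ex.phi, abs=1e-12)

    def test_seed_determinism(self, rng):
        f = lambda Z: Z.sum(axis=1) ** 2
        x = rng.normal(size=4)
        bg = rng.normal(size=(6, 4))
        a = sampling_shapley(f, x, bg, n_permutations=50, seed=7)
        b = sampling_shapley(f, x, bg, n_permutations=50, seed=7)
        assert np.array_equal(a.phi, b.phi)


class TestTreeShapley:
    def test_stump_equals_exact_shapley_with_training_background(self, rng):
        """For a depth-1 stump the path-dependent game coincides with
        interventional marginalization over the training rows."""
        X = rng.normal(size=(40, 1))
        y = (X[:, 0] > 0.2).astype(float)
        stump = fit_cart(X, y, max_depth=1, min_samples_split=2, min_samples_leaf=1)
        ens = TreeEnsemble([stump], "average_probability", n_features=1)
        for x in (np.array([-1.0]), np.array([1.0])):
            tv = tree_shapley(ens, x)[0]
            ev = exact_shapley(lambda Z: ens.predict_proba(Z), x, X)
            assert tv.phi == pytest.approx(ev.phi, abs=1e-10)
            assert tv.base_value == pytest.approx(ev.base_value, abs=1e-10)

    def test_depth_two_tree_matches_coalition_enumeration(self, rng):
        X = rng.normal(size=(60, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(float)
        t = fit_cart(X, y, max_depth=2, min_samples_split=2, min_samples_leaf=1)
        ens = TreeEnsemble([t], "average_probability", n_features=2)
        for _ in range(5):
            x = rng.normal(size=2)
            got = tree_shapley(ens, x)[0].phi
            want = brute_force_tree_shapley(t, x, 2)
            assert got == pytest.approx(want, abs=1e-10)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_random_trees_match_enumeration(self, seed):
        """Property sweep: random trees with up to 3 features and depth 3,
        including repeated features along a path."""
        rng = np.random.default_rng(seed)
        t = random_tree(rng, n_features=3, depth=3)
        ens = TreeEnsemble([t], "average_probability", n_features=3)
        x = rng.normal(size=3)
        got = tree_shapley(ens, x)[0]
        want = brute_force_tree_shapley(t, x, 3)
        assert got.phi == pytest.approx(want, abs=1e-9)
        assert got.total == pytest.approx(float(t.predict(x[None])[0]), abs=1e-9)

    def test_local_accuracy_on_boosted_ensemble(self, rng):
        X = rng.normal(size=(100, 5))
        y = (X[:, 0] - X[:, 3] > 0).astype(float)
        g = fit_gbm(X, y, n_rounds=15, learning_rate=0.2, max_depth=3, seed=0)
        rows = rng.normal(size=(100, 5))
        attrs = tree_shapley(g, rows)
        margins = g.predict_margin(rows)
        for av, m in zip(attrs, margins):
            assert av.total == pytest.approx(float(m), abs=1e-10)

    def test_ensemble_attribution_is_sum_of_tree_attributions(self, rng):
        X = rng.normal(size=(50, 3))
        y = (X[:, 0] + X[:, 1] > 0).astype(float)
        g = fit_gbm(X, y, n_rounds=4, learning_rate=0.3, max_depth=2, seed=1)
        x = rng.normal(size=3)
        whole = tree_shapley(g, x)[0].phi
        parts = np.zeros(3)
        for t in g.trees:
            single = TreeEnsemble([t], "additive_margin", n_features=3)
            parts += tree_shapley(single, x)[0].phi
        assert whole == pytest.approx(parts, abs=1e-10)

    def test_monotone_stump_attribution_has_sign_of_output_shift(self, rng):
        X = np.linspace(-1, 1, 20)[:, None]
        y = (X[:, 0] > 0).astype(float)
        stump = fit_cart(X, y, max_depth=1, min_samples_split=2, min_samples_leaf=1)
        ens = TreeEnsemble([stump], "average_probability", n_features=1)
        av_hi = tree_shapley(ens, np.array([0.9]))[0]
        av_lo = tree_shapley(ens, np.array([-0.9]))[0]
        assert av_hi.phi[0] > 0 > av_lo.phi[0]

    def test_missing_covers_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(float)
        t = fit_cart(X, y, max_depth=2)
        t.cover = np.zeros_like(t.cover)
        ens = TreeEnsemble([t], "average_probability", n_features=2)
        with pytest.raises(ValueError, match="cover"):
            tree_shapley(ens, X[:1])


class TestInteraction:
    def test_additive_model_has_zero_interaction(self, rng):
        f = lambda Z: 3 * Z[:, 0] - Z[:, 1] + 0.5 * Z[:, 2]
        x = rng.normal(size=3)
        bg = rng.normal(size=(6, 3))
        for i, j in itertools.combinations(range(3), 2):
            assert interaction_value(f, x, i, j, bg) == pytest.approx(0.0, abs=1e-12)

    def test_product_model_matches_direct_enumeration(self):
        f = lambda Z: Z[:, 0] * Z[:, 1]
        x = np.array([1.0, 1.0])
        bg = np.array([[-1.0, -1], [1, 1], [-1, 1], [1, -1]])
        # M=2: the only S is the empty set, weight 0!0!/(2*1!) = 1/2, and
        # delta = f(1,1) - f(1, bg) - f(bg, 1) + f(bg, bg) = 1 - 0 - 0 + 0
        assert interaction_value(f, x, 0, 1, bg) == pytest.approx(0.5)

    def test_symmetry_in_the_feature_pair(self, rng):
        f = lambda Z: Z[:, 0] * Z[:, 1] ** 2 + Z[:, 2]
        x = rng.normal(size=3)
        bg = rng.normal(size=(5, 3))
        assert interaction_value(f, x, 0, 1, bg) == pytest.approx(
            interaction_value(f, x, 1, 0, bg), abs=1e-12)

    def test_same_feature_twice_rejected(self):
        f = lambda Z: Z.sum(axis=1)
        with pytest.raises(ValueError, match="distinct"):
            interaction_value(f, np.zeros(3), 1, 1, np.zeros((1, 3)))
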