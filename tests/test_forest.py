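import itertools

import numpy as np
import pytest

from signgrn.forest import (
    ForestParams,
    RegressionTree,
    fit_genie3_forest,
    fit_tree,
    random_input_importance,
    variance_importance,
)


def _wvar_sse(y, w):
    """Weighted SSE about the weighted mean (oracle helper)."""
    sw = w.sum()
    mean = (w * y).sum() / sw
    return (w * (y - mean) ** 2).sum()


def _brute_force_best_split(X, y, w):
    """Enumerate every feature and every midpoint threshold; return
    (feature, threshold, sse_reduction) of the best split."""
    best = None
    total = _wvar_sse(y, w)
    for f in range(X.shape[1]):
        xs = np.unique(X[:, f])
        for lo, hi in zip(xs[:-1], xs[1:]):
            thr = 0.5 * (lo + hi)
            mask = X[:, f] <= thr
            red = total - _wvar_sse(y[mask], w[mask]) - _wvar_sse(y[~mask], w[~mask])
            if best is None or red > best[2]:
                best = (f, thr, red)
    return best


class TestFitTree:
    def test_constant_outputs_single_leaf(self, rng):
        X = rng.random((20, 3))
        tree = fit_tree(X, np.full(20, 4.2), np.ones(20), n_test=2, rng=rng)
        assert tree.n_nodes == 1
        np.testing.assert_allclose(tree.predict(X), 4.2)

    def test_memorizes_distinct_examples(self, rng):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1.0, 5.0, 2.0, 9.0])
        tree = fit_tree(X, y, np.ones(4), n_test=1, rng=rng)
        np.testing.assert_allclose(tree.predict(X), y)

    def test_best_split_matches_brute_force_oracle(self, rng):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 0.0, 3.0])
        w = np.array([1.0, 1.0, 2.0])
        tree = fit_tree(X, y, w, n_test=1, rng=rng)
        f, thr, red = _brute_force_best_split(X, y, w)
        assert tree.feature[0] == f
        assert tree.threshold[0] == pytest.approx(thr)
        # recorded gain is variance reduction = SSE reduction / node weight
        assert tree.gain[0] * tree.weight[0] == pytest.approx(red)

    @pytest.mark.parametrize("seed", range(5))
    def test_root_split_matches_oracle_random_data(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((30, 4))
        y = rng.random(30)
        w = rng.uniform(0.1, 2.0, 30)
        tree = fit_tree(X, y, w, n_test=4, rng=rng)  # all features sampled
        f, thr, red = _brute_force_best_split(X, y, w)
        assert tree.feature[0] == f
        assert tree.threshold[0] == pytest.approx(thr)
        assert tree.gain[0] * tree.weight[0] == pytest.approx(red)

    def test_leaf_values_are_weighted_means(self, rng):
        X = rng.random((40, 2))
        y = rng.random(40)
        w = rng.uniform(0.1, 3.0, 40)
        tree = fit_tree(X, y, w, n_test=2, n_hmax=2, rng=rng)
        pred = tree.predict(X)
        # group examples by leaf and verify each prediction is the
        # weighted mean of its group
        for p in np.unique(pred):
            mask = pred == p
            assert p == pytest.approx((w[mask] * y[mask]).sum() / w[mask].sum())

    def test_height_limit(self, rng):
        X = rng.random((200, 2))
        y = rng.random(200)
        tree = fit_tree(X, y, np.ones(200), n_test=2, n_hmax=3, rng=rng)
        assert tree.n_nodes <= 2 ** 4 - 1

    def test_gain_nonnegative(self, rng):
        X = rng.random((50, 3))
        y = rng.random(50)
        tree = fit_tree(X, y, np.ones(50), n_test=2, rng=rng)
        assert np.all(tree.gain >= 0)

    def test_constant_weight_scaling_same_structure(self):
        # c = 4.0 is exactly representable, so mathematically tied splits
        # stay tied in floating point and the structures match exactly
        X = np.random.default_rng(0).random((60, 4))
        y = np.random.default_rng(1).random(60)
        t1 = fit_tree(X, y, np.ones(60), n_test=2, rng=np.random.default_rng(99))
        t2 = fit_tree(X, y, np.full(60, 4.0), n_test=2,
                      rng=np.random.default_rng(99))
        np.testing.assert_array_equal(t1.feature, t2.feature)
        np.testing.assert_allclose(t1.threshold, t2.threshold, equal_nan=True)
        np.testing.assert_allclose(t1.value, t2.value)

    def test_constant_weight_scaling_same_predictions(self):
        # a non-representable constant may flip exactly-tied deep splits
        # through rounding; predictions must still agree closely
        X = np.random.default_rng(0).random((60, 4))
        y = np.random.default_rng(1).random(60)
        t1 = fit_tree(X, y, np.ones(60), n_test=2, rng=np.random.default_rng(99))
        t2 = fit_tree(X, y, np.full(60, 3.7), n_test=2,
                      rng=np.random.default_rng(99))
        np.testing.assert_allclose(t1.predict(X), t2.predict(X))
        grid = np.random.default_rng(2).random((200, 4))
        assert np.mean(t1.predict(grid) != t2.predict(grid)) < 0.2

    def test_sample_order_invariance(self):
        """Permuting example order (same rng draws) yields identical
        predictions."""
        base = np.random.default_rng(0)
        X = base.random((50, 3))
        y = base.random(50)
        w = base.uniform(0.5, 1.5, 50)
        perm = base.permutation(50)
        t1 = fit_tree(X, y, w, n_test=2, rng=np.random.default_rng(5))
        t2 = fit_tree(X[perm], y[perm], w[perm], n_test=2,
                      rng=np.random.default_rng(5))
        grid = base.random((100, 3))
        np.testing.assert_allclose(t1.predict(grid), t2.predict(grid))

    def test_all_zero_weights_rejected(self, rng):
        with pytest.raises(ValueError, match="weights"):
            fit_tree(np.ones((3, 2)), np.ones(3), np.zeros(3), n_test=1, rng=rng)

    def test_non_finite_rejected(self, rng):
        X = np.ones((3, 2))
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            fit_tree(X, np.ones(3), np.ones(3), n_test=1, rng=rng)

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_tree(np.empty((0, 2)), np.empty(0), np.empty(0), n_test=1, rng=rng)

    def test_serialization_roundtrip(self, rng):
        X = rng.random((30, 3))
        tree = fit_tree(X, rng.random(30), np.ones(30), n_test=2, rng=rng)
        clone = RegressionTree.from_dict(tree.to_dict())
        np.testing.assert_allclose(tree.predict(X), clone.predict(X))
        np.testing.assert_array_equal(tree.feature, clone.feature)


class TestGenie3Forest:
    def test_tree_count(self, rng):
        X = rng.random((30, 4))
        params = ForestParams(n_tree=1, n_subtree=50, n_rnd=1)
        trees = fit_genie3_forest(X, rng.random(30), np.ones(30), params, rng)
        assert len(trees) == 50

    def test_informative_feature_wins(self, rng):
        """X2 = 2*X1 with noise features: feature 0 (the driver) tops both
        importance measures."""
        x1 = rng.random(120)
        X = np.column_stack([x1, rng.random(120), rng.random(120)])
        y = 2.0 * x1
        params = ForestParams(n_tree=1, n_subtree=20, n_rnd=1, n_test=2)
        trees = fit_genie3_forest(X, y, np.ones(120), params, rng)
        vi = variance_importance(trees, 3)
        assert vi[0] == vi.max() and vi[0] > 0
        ri = random_input_importance(trees, X, y, np.ones(120), rng)
        assert ri[0] == ri.max() and ri[0] > 0

    def test_empty_sample_rejected(self, rng):
        params = ForestParams(n_tree=1, n_subtree=2, n_rnd=1)
        with pytest.raises(ValueError):
            fit_genie3_forest(np.empty((0, 3)), np.empty(0), np.empty(0),
                              params, rng)


class TestVarianceImportance:
    def test_unused_feature_zero(self, rng):
        X = np.column_stack([np.linspace(0, 1, 20), np.zeros(20)])
        tree = fit_tree(X, np.linspace(0, 1, 20), np.ones(20), n_test=2, rng=rng)
        vi = variance_importance([tree], 2)
        assert vi[1] == 0.0

    def test_single_split_hand_computed(self):
        """One split on feature 0: importance equals the hand-computed SSE
        reduction."""
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        w = np.array([1.0, 1.0, 1.0, 1.0])
        tree = fit_tree(X, y, w, n_test=1, n_hmax=1, rng=np.random.default_rng(0))
        assert tree.n_nodes == 3
        # total SSE = 1.0 (mean 0.5, four deviations of 0.5^2)
        # both halves pure -> reduction = 1.0; node weight = 4
        vi = variance_importance([tree], 1)
        assert vi[0] == pytest.approx(1.0)

    def test_order_permutation_invariant(self, rng):
        X = rng.random((40, 3))
        y = rng.random(40)
        trees = [fit_tree(X, y, np.ones(40), n_test=2, rng=rng) for _ in range(5)]
        vi = variance_importance(trees, 3)
        vi_rev = variance_importance(trees[::-1], 3)
        np.testing.assert_allclose(vi, vi_rev)

    def test_total_mass_conserved(self, rng):
        """Sum of scores over features equals the total recorded reduction
        mass averaged over trees."""
        X = rng.random((50, 4))
        y = rng.random(50)
        trees = [fit_tree(X, y, np.ones(50), n_test=2, rng=rng) for _ in range(3)]
        vi = variance_importance(trees, 4)
        expected = np.mean([
            (t.gain[t.feature != -1] * t.weight[t.feature != -1]).sum()
            for t in trees
        ])
        assert vi.sum() == pytest.approx(expected)


class TestRandomInputImportance:
    def test_unused_feature_exactly_zero(self, rng):
        X = np.column_stack([np.linspace(0, 1, 20), rng.random(20)])
        y = np.linspace(0, 1, 20)
        tree = fit_tree(X[:, :1], y, np.ones(20), n_test=1, rng=rng)
        # widen tree's feature space conceptually: build on 2 cols instead
        tree2 = fit_tree(np.column_stack([X[:, 0], np.zeros(20)]), y,
                         np.ones(20), n_test=1, rng=rng)
        scores = random_input_importance([tree2], X, y, np.ones(20), rng)
        assert scores[1] == 0.0

    def test_informative_feature_positive(self, rng):
        X = np.linspace(0, 1, 16).reshape(-1, 1)
        y = np.linspace(0, 2, 16)
        tree = fit_tree(X, y, np.ones(16), n_test=1, rng=rng)
        scores = random_input_importance([tree], X, y, np.ones(16), rng)
        assert scores[0] > 0

    def test_matches_exhaustive_permutation_oracle(self):
        """Monte-Carlo mean over many seeded calls converges to the exact
        average over all 4! column permutations."""
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        w = np.array([1.0, 2.0, 1.0, 2.0])
        tree = fit_tree(X, y, w, n_test=1, n_hmax=1, rng=np.random.default_rng(0))

        def wmse(pred):
            return (w * (pred - y) ** 2).sum() / w.sum()

        base = wmse(tree.predict(X))
        exact = np.mean([
            wmse(tree.predict(X[list(p), :])) - base
            for p in itertools.permutations(range(4))
        ])
        rng = np.random.default_rng(777)
        n_rep = 3000
        mc = np.mean([
            random_input_importance([tree], X, y, w, rng)[0]
            for _ in range(n_rep)
        ])
        # 3-sigma band of the Monte-Carlo mean
        spread = np.std([
            wmse(tree.predict(X[list(p), :])) - base
            for p in itertools.permutations(range(4))
        ])
        assert abs(mc - exact) < 3 * spread / np.sqrt(n_rep) + 1e-12


class TestForestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ForestParams(n_tree=0)
        with pytest.raises(ValueError):
            ForestParams(n_subtree=0)
        with pytest.raises(ValueError):
            ForestParams(n_rnd=0)

    def test_paper_profile_values(self):
        p = ForestParams.paper()
        assert (p.n_tree, p.n_subtree, p.n_hmax, p.n_rnd) == (1000, 50, 32, 100)

    def test_n_test_default_is_third_of_features(self):
        p = ForestParams.paper()
        # ceil((N-1)/3) candidate features for an N-gene problem
        assert p.resolve_n_test(9) == 3    # N=10
        assert p.resolve_n_test(10) == 4
        assert p.resolve_n_test(1) == 1
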