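"""Deep-regression-forest math: routing, prediction, likelihood, leaf updates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from feddrf.drf import (
    LeafDistribution,
    TreeTopology,
    drf_nll,
    drf_nll_grad_s,
    forest_nll,
    forest_predict,
    init_leaves,
    routing_probabilities,
    tree_predict,
    update_forest_leaves,
    update_leaves,
)


def enumerate_paths(topo):
    """Brute-force (node, went_left) paths root->leaf, breadth-first indexing."""
    paths = []
    for leaf in range(topo.n_leaves):
        bits = format(leaf, f"0{topo.depth - 1}b")
        v, path = 0, []
        for b in bits:
            path.append((v, b == "0"))
            v = 2 * v + 1 + int(b)
        paths.append(path)
    return paths


def oracle_leaf_probs(s, topo):
    P = np.ones(topo.n_leaves)
    for leaf, path in enumerate(enumerate_paths(topo)):
        for v, left in path:
            P[leaf] *= s[v] if left else 1.0 - s[v]
    return P


class TestTopology:
    def test_internal_plus_one_equals_leaves(self):
        for d in range(2, 7):
            t = TreeTopology(d)
            assert t.n_internal + 1 == t.n_leaves

    def test_two_trees_depth3_consume_six_outputs(self):
        assert TreeTopology(3).n_outputs(n_trees=2) == 6

    def test_depth_below_two_rejected(self):
        with pytest.raises(ValueError):
            TreeTopology(1)


class TestRouting:
    def test_uniform_split(self):
        P = routing_probabilities([0.5, 0.5, 0.5], TreeTopology(3))
        assert np.allclose(P, 0.25)

    def test_saturated_routing_hits_leftmost_leaf(self):
        P = routing_probabilities([1.0, 1.0, 0.3], TreeTopology(3))
        assert np.allclose(P, [1.0, 0.0, 0.0, 0.0])

    def test_worked_example(self):
        P = routing_probabilities([0.8, 0.6, 0.3], TreeTopology(3))
        assert np.allclose(P, [0.48, 0.32, 0.06, 0.14], atol=1e-12)

    @given(st.integers(2, 6), st.integers(0, 10_000))
    def test_probabilities_sum_to_one(self, depth, seed):
        topo = TreeTopology(depth)
        s = np.random.default_rng(seed).uniform(size=topo.n_internal)
        P = routing_probabilities(s, topo)
        assert abs(P.sum() - 1.0) < 1e-9
        assert (P >= 0).all() and (P <= 1).all()

    @given(st.integers(2, 6), st.integers(0, 500))
    def test_matches_path_enumeration_oracle(self, depth, seed):
        topo = TreeTopology(depth)
        s = np.random.default_rng(seed).uniform(size=topo.n_internal)
        assert np.allclose(routing_probabilities(s, topo), oracle_leaf_probs(s, topo),
                           atol=1e-12)

    def test_contract_errors(self):
        topo = TreeTopology(3)
        with pytest.raises(ValueError):
            routing_probabilities([0.5, 0.5], topo)
        with pytest.raises(ValueError):
            routing_probabilities([0.5, 1.5, 0.5], topo)


class TestPrediction:
    def test_point_mass(self):
        assert tree_predict([1.0, 0, 0, 0], [5.0, 1, 2, 3]) == pytest.approx(5.0)

    def test_worked_dot_product(self):
        assert tree_predict([0.48, 0.32, 0.06, 0.14], [1, 2, 3, 4]) == pytest.approx(1.86)

    def test_equal_leaves_give_common_mean(self, rng):
        s = rng.uniform(size=7)
        P = routing_probabilities(s, TreeTopology(4))
        assert tree_predict(P, np.full(8, 2.5)) == pytest.approx(2.5)

    def test_forest_mean_and_symmetry(self):
        assert forest_predict([1.0, 3.0]) == pytest.approx(2.0)
        assert forest_predict([3.0, 1.0]) == forest_predict([1.0, 3.0])
        assert forest_predict([7.0]) == pytest.approx(7.0)
        with pytest.raises(ValueError):
            forest_predict([])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            tree_predict([0.5, 0.5], [1.0, 2.0, 3.0])


class TestNLL:
    def test_single_leaf_unit_density_gives_zero_loss(self):
        var = 1.0 / (2 * np.pi)
        loss = drf_nll([2.0, 2.0], np.ones((2, 1)), np.array([2.0]), np.array([var]))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_underflow_is_clamped_not_nan(self):
        loss = drf_nll([1e6], np.array([[0.5, 0.5]]), np.zeros(2), np.full(2, 1e-4))
        assert np.isfinite(loss)

    def test_mixture_bound_against_best_component(self, rng):
        # -log sum P_l g_l <= -log(P_max g_best): mixture never worse than
        # its best-weighted component alone
        for _ in range(20):
            topo = TreeTopology(3)
            s = rng.uniform(0.05, 0.95, size=3)
            P = routing_probabilities(s, topo)
            mu, var = rng.normal(size=4), rng.uniform(0.2, 2.0, size=4)
            y = rng.normal()
            loss = drf_nll([y], P, mu, var)
            logg = -0.5 * (np.log(2 * np.pi * var) + (y - mu) ** 2 / var)
            assert loss <= -np.max(np.log(P) + logg) + 1e-9

    @pytest.mark.parametrize("depth,trees", [(3, 1), (4, 2)])
    def test_gradient_matches_finite_differences(self, depth, trees, rng):
        topo = TreeTopology(depth)
        leaves = LeafDistribution(rng.normal(size=(trees, topo.n_leaves)),
                                  rng.uniform(0.2, 2.0, size=(trees, topo.n_leaves)))
        y = rng.normal(size=4)
        S = rng.uniform(0.05, 0.95, size=(4, trees * topo.n_internal))
        _, grad = drf_nll_grad_s(y, S, topo, leaves)
        eps = 1e-6
        for i in range(S.shape[0]):
            for j in range(S.shape[1]):
                Sp, Sm = S.copy(), S.copy()
                Sp[i, j] += eps
                Sm[i, j] -= eps
                fd = (drf_nll_grad_s(y, Sp, topo, leaves)[0]
                      - drf_nll_grad_s(y, Sm, topo, leaves)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(fd, abs=1e-5)


class TestLeaves:
    def test_init_is_standard_normal_shifted_to_one(self):
        leaves = init_leaves(TreeTopology(4), n_trees=3)
        assert (leaves.mu == 1.0).all()
        assert (leaves.var == 1.0).all()
        again = init_leaves(TreeTopology(4), n_trees=3)
        assert np.array_equal(leaves.mu, again.mu) and np.array_equal(leaves.var, again.var)

    def test_single_leaf_recovers_sample_moments(self, rng):
        y = rng.normal(2.0, 1.5, size=50)
        mu, var = update_leaves(np.ones((50, 1)), y, np.array([1.0]), np.array([1.0]),
                                n_iter=1)
        assert mu[0] == pytest.approx(y.mean(), abs=1e-12)
        assert var[0] == pytest.approx(y.var(), abs=1e-12)

    def test_one_hot_routing_recovers_cluster_means(self, rng):
        y = np.concatenate([np.zeros(30), np.full(30, 10.0)]) + rng.normal(0, 1e-8, 60)
        P = np.zeros((60, 2))
        P[:30, 0] = 1.0
        P[30:, 1] = 1.0
        mu, _ = update_leaves(P, y, np.array([4.0, 6.0]), np.array([1.0, 1.0]), n_iter=5)
        assert mu[0] == pytest.approx(0.0, abs=1e-6)
        assert mu[1] == pytest.approx(10.0, abs=1e-6)

    def test_nll_never_increases_across_iterations(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            topo = TreeTopology(3)
            s = rng.uniform(size=(40, 3))
            P = routing_probabilities(s, topo)
            y = rng.normal(size=40)
            mu = rng.normal(size=4)
            var = rng.uniform(0.3, 2.0, size=4)
            prev = drf_nll(y, P, mu, var)
            for _ in range(10):
                mu, var = update_leaves(P, y, mu, var, n_iter=1)
                cur = drf_nll(y, P, mu, var)
                assert cur <= prev + 1e-9
                prev = cur

    def test_starved_leaf_keeps_parameters(self):
        P = np.zeros((10, 2))
        P[:, 0] = 1.0  # leaf 1 never reached
        y = np.linspace(0, 1, 10)
        mu, var = update_leaves(P, y, np.array([0.0, 42.0]), np.array([1.0, 9.0]), n_iter=3)
        assert mu[1] == 42.0 and var[1] == 9.0

    def test_forest_leaf_update_lowers_forest_nll(self, rng):
        topo = TreeTopology(3)
        leaves = init_leaves(topo, 2)
        y = rng.normal(1.0, 2.0, size=80)
        S = rng.uniform(0.1, 0.9, size=(80, 6))
        before = forest_nll(y, S, topo, leaves)
        after = forest_nll(y, S, topo,
                           update_forest_leaves(y, S, topo, leaves, n_iter=3))
        assert after <= before + 1e-9

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            update_leaves(np.empty((0, 2)), np.empty(0), np.zeros(2), np.ones(2))
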