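"""Multivariate regression tree core: SS, split search, growth, pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from commtrees.tree import (GrowControl, MultivariateRegressionTree, SplitRule,
                            best_split, enumerate_level_sets, grow_tree,
                            node_ss, relative_error)
from conftest import zero_noise_fixture
from oracles import brute_force_best_split, two_pass_ss

SMALL = GrowControl(min_node_size=1, min_split_size=2, min_improvement=0.0)


class TestNodeSS:
    def test_single_row_is_zero(self):
        assert node_ss(np.array([[3.0, 4.0]])) == 0.0

    def test_hand_computed_two_rows(self):
        # centroid (1, 0); each row at squared distance 1
        assert node_ss(np.array([[0.0, 0.0], [2.0, 0.0]])) == pytest.approx(2.0)

    def test_matches_two_pass_oracle(self, rng):
        for _ in range(25):
            rows = rng.normal(size=(rng.integers(1, 12), rng.integers(1, 5)))
            assert node_ss(rows) == pytest.approx(two_pass_ss(rows), abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            node_ss(np.empty((0, 2)))


class TestBestSplit:
    def test_separates_two_response_plateaus(self):
        Y = np.array([[0.0], [0.0], [10.0], [10.0]])
        X = pd.DataFrame({"x": [1.0, 2.0, 8.0, 9.0]})
        rule = best_split(Y, X, SMALL)
        assert rule.variable == "x"
        assert 2.0 < rule.threshold < 8.0
        assert rule.improvement == pytest.approx(100.0)

    def test_constant_response_yields_none(self):
        Y = np.full((8, 2), 3.0)
        X = pd.DataFrame({"x": np.arange(8.0)})
        assert best_split(Y, X, GrowControl(1, 2, 0.001)) is None

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 15))
            q = int(rng.integers(1, 4))
            Y = rng.normal(size=(n, q))
            kinds = [rng.choice(["numeric", "unordered"]) for _ in range(2)]
            data, columns = {}, []
            for j, kind in enumerate(kinds):
                name = f"v{j}"
                if kind == "numeric":
                    vals = rng.integers(0, 6, n).astype(float)
                    data[name] = vals
                    columns.append((name, "numeric", vals, None))
                else:
                    levels = ["a", "b", "c", "d"][: int(rng.integers(2, 5))]
                    vals = rng.choice(levels, n)
                    data[name] = pd.Categorical(vals, categories=levels)
                    columns.append((name, "unordered", vals, levels))
            X = pd.DataFrame(data)
            expected = brute_force_best_split(Y, columns, min_node=1)
            rule = best_split(Y, X, SMALL)
            if expected is None or expected[3] <= 1e-10:
                continue
            assert rule is not None
            assert rule.variable == expected[0]
            assert rule.improvement == pytest.approx(expected[3], abs=1e-9)
            if expected[1] == "numeric":
                assert rule.threshold == pytest.approx(expected[2])
            else:
                assert rule.left_levels == expected[2] or \
                    rule.left_levels == set(columns[
                        [c[0] for c in columns].index(expected[0])][3]) - expected[2]

    def test_missing_values_routed_to_majority_side(self):
        Y = np.array([[0.0], [0.0], [0.0], [10.0], [10.0], [5.0]])
        X = pd.DataFrame({"x": [1.0, 1.5, 2.0, 8.0, 9.0, np.nan]})
        tree = grow_tree(Y, X, GrowControl(1, 2, 0.0, max_depth=1))
        rule = tree.root.rule
        assert rule.missing_side == "left"  # left child has 3 observed rows
        assert tree.root.left.n == 4


class TestSplitGeometry:
    def test_level_set_count_is_2_pow_lminus1_minus_1(self):
        for L in range(2, 7):
            levels = [f"l{i}" for i in range(L)]
            assert len(enumerate_level_sets(levels)) == 2 ** (L - 1) - 1

    def test_ordered_variable_splits_are_contiguous(self):
        # an ordered factor with a non-monotone response: the fitted rule
        # must still be a threshold in the declared order
        rng = np.random.default_rng(0)
        lev = ["low", "medium", "high"]
        X = pd.DataFrame({"g": pd.Categorical(
            rng.choice(lev, 30), categories=lev, ordered=True)})
        Y = rng.normal(size=(30, 2))
        rule = best_split(Y, X, SMALL)
        if rule is not None:
            assert rule.kind == "ordered"
            assert rule.threshold is not None
            assert rule.left_levels is None

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_between_group_ss_identity(self, seed):
        # SS_parent - SS_left - SS_right = (nl*nr/n) * ||mean_l - mean_r||^2
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        q = int(rng.integers(1, 5))
        Y = rng.normal(size=(n, q))
        cut = int(rng.integers(1, n))
        left, right = Y[:cut], Y[cut:]
        delta = node_ss(Y) - node_ss(left) - node_ss(right)
        nl, nr = len(left), len(right)
        d = left.mean(axis=0) - right.mean(axis=0)
        assert delta == pytest.approx(nl * nr / n * float(d @ d), abs=1e-9)


class TestGrowTree:
    def test_recovers_zero_noise_partition(self):
        Y, X, sites, region = zero_noise_fixture()
        tree = grow_tree(Y, X, GrowControl(5, 10, 0.001))
        assert tree.n_leaves == 4
        assert relative_error(tree) == pytest.approx(0.0, abs=1e-12)
        leaf_of = tree.apply(X)
        # fitted leaves coincide with the true regions
        assert len(set(zip(region, leaf_of))) == 4

    def test_too_few_rows_gives_root_only_tree(self):
        Y = np.array([[1.0], [2.0], [3.0]])
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        tree = grow_tree(Y, X, GrowControl(min_node_size=5, min_split_size=10))
        assert tree.n_leaves == 1
        assert relative_error(tree) == 1.0

    def test_deterministic_serialization(self, rng):
        Y = rng.normal(size=(30, 3))
        X = pd.DataFrame({"a": rng.normal(size=30), "b": rng.integers(0, 3, 30)})
        t1 = grow_tree(Y, X, SMALL)
        t2 = grow_tree(Y, X, SMALL)
        assert t1.to_json() == t2.to_json()

    def test_row_permutation_invariance(self, rng):
        Y = rng.normal(size=(40, 2))
        X = pd.DataFrame({"a": rng.normal(size=40),
                          "b": rng.choice(["u", "v", "w"], 40)})
        perm = rng.permutation(40)
        t1 = grow_tree(Y, X, GrowControl(3, 6, 0.001))
        t2 = grow_tree(Y[perm], X.iloc[perm].reset_index(drop=True),
                       GrowControl(3, 6, 0.001))
        def rules(t):
            return [(n.rule.variable, n.rule.threshold, n.rule.left_levels, n.n)
                    for n in t.nodes if not n.is_leaf]
        assert rules(t1) == rules(t2)

    def test_ss_decomposition_identity_on_fitted_tree(self, rng):
        Y = rng.normal(size=(50, 3))
        X = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        tree = grow_tree(Y, X, GrowControl(3, 6, 0.0))
        leaf_ss = sum(l.ss for l in tree.leaves())
        improvements = sum(n.rule.improvement for n in tree.nodes if not n.is_leaf)
        assert leaf_ss + improvements == pytest.approx(tree.root_ss, abs=1e-9)


class TestPruning:
    def test_root_only_tree_has_length_one_sequence(self):
        Y = np.array([[1.0], [2.0]])
        X = pd.DataFrame({"x": [0.0, 1.0]})
        tree = grow_tree(Y, X, GrowControl(5, 10))
        assert len(tree.prune_steps) == 1
        assert tree.prune_steps[0].n_leaves == 1

    def test_sequence_is_nested_and_alpha_increasing(self):
        Y, X, _, _ = zero_noise_fixture()
        tree = grow_tree(Y, X, GrowControl(5, 10, 0.001))
        steps = tree.prune_steps
        assert steps[-1].n_leaves == 1
        for a, b in zip(steps[:-1], steps[1:]):
            assert b.alpha >= a.alpha
            assert b.n_leaves < a.n_leaves
            assert a.collapsed <= b.collapsed  # nested subtrees

    def test_re_non_increasing_with_size(self, rng):
        Y = rng.normal(size=(60, 3))
        X = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60)})
        tree = grow_tree(Y, X, GrowControl(3, 6, 0.0))
        res = [s.relative_error(tree.root_ss) for s in tree.prune_steps]
        assert all(b >= a - 1e-12 for a, b in zip(res[:-1], res[1:]))
        assert res[-1] == pytest.approx(1.0)

    def test_relative_error_matches_anova_decomposition(self, rng):
        Y = rng.normal(size=(45, 2))
        X = pd.DataFrame({"a": rng.normal(size=45)})
        tree = grow_tree(Y, X, GrowControl(3, 6, 0.0))
        leaf_of = tree.apply(X)
        grand = Y.mean(axis=0)
        between = sum(len(Y[leaf_of == l]) *
                      float(((Y[leaf_of == l].mean(axis=0) - grand) ** 2).sum())
                      for l in set(leaf_of))
        assert relative_error(tree) == pytest.approx(
            1.0 - between / node_ss(Y), abs=1e-9)


class TestEstimatorFacade:
    def test_fit_predict_shapes_and_params(self):
        Y, X, _, _ = zero_noise_fixture()
        est = MultivariateRegressionTree(min_node_size=5, min_split_size=10)
        est.fit(X, Y)
        assert est.r_squared_ == pytest.approx(1.0)
        assert est.predict(X).shape == Y.shape
        params = est.get_params()
        assert params["min_node_size"] == 5
        clone = MultivariateRegressionTree(**params).fit(X, Y)
        assert clone.n_leaves_ == est.n_leaves_

    def test_size_parameter_prunes_predictions(self):
        Y, X, _, _ = zero_noise_fixture()
        est = MultivariateRegressionTree(size=2).fit(X, Y)
        assert est.n_leaves_ == 2
        assert len(np.unique(est.apply(X))) == 2

    def test_export_round_trip_text_and_json(self):
        Y, X, _, _ = zero_noise_fixture()
        tree = grow_tree(Y, X)
        text = tree.to_text()
        assert "n=60" in text and "root" in text
        d = tree.to_dict()
        assert d["tree"]["n"] == 60
        assert d["pruning_sequence"][-1]["n_leaves"] == 1
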