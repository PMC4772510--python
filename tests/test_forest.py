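"""Tree induction: GINI splitting, crossover formula, hybrid construction."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rfscreen as rf
from rfscreen.forest import _rng

from conftest import split_table


def brute_force_best_split(X, y, rows, features, min_gain=0.0):
    """Independent exhaustive enumeration of every (feature, midpoint) pair."""
    rows = np.asarray(rows)
    counts = np.bincount(y[rows], minlength=2)
    parent = rf.gini_impurity(counts)
    best = None
    for feat in sorted(features):
        vals = sorted(set(X[rows, feat]))
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2.0
            left = rows[X[rows, feat] <= thr]
            right = rows[X[rows, feat] > thr]
            gl = rf.gini_impurity(np.bincount(y[left], minlength=2))
            gr = rf.gini_impurity(np.bincount(y[right], minlength=2))
            gain = parent - (left.size * gl + right.size * gr) / rows.size
            if best is None or gain > best[2]:
                best = (feat, thr, gain)
    if best is None or best[2] <= min_gain:
        return None
    return best


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 0), 0.0), ((5, 5), 0.5), ((3, 1), 0.375), ((1, 3), 0.375)],
    )
    def test_known_values(self, counts, expected):
        assert rf.gini_impurity(counts) == pytest.approx(expected, abs=1e-15)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rf.gini_impurity((0, 0))

    @given(st.integers(0, 1000), st.integers(0, 1000))
    @settings(deadline=None, max_examples=100)
    def test_range_and_purity(self, a, b):
        if a + b == 0:
            return
        g = rf.gini_impurity((a, b))
        assert 0.0 <= g <= 0.5
        assert (g == 0.0) == (a == 0 or b == 0)


class TestBestSplit:
    def test_simple_separable(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 1])
        feat, thr, gain = rf.best_split(X, y, np.arange(4), [0])
        assert (feat, thr) == (0, 2.5)
        assert gain == pytest.approx(0.5)

    def test_pure_node_no_split(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([1, 1, 1])
        assert rf.best_split(X, y, np.arange(3), [0], min_gain=1e-7) is None

    def test_constant_feature_no_split(self):
        X = np.ones((4, 1))
        y = np.array([0, 1, 0, 1])
        assert rf.best_split(X, y, np.arange(4), [0]) is None

    def test_tie_breaks_to_lowest_feature(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([col, col])
        y = np.array([0, 0, 1, 1])
        feat, thr, _ = rf.best_split(X, y, np.arange(4), [0, 1])
        assert (feat, thr) == (0, 2.5)

    def test_binary_column_threshold_is_half(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        _, thr, _ = rf.best_split(X, y, np.arange(4), [0])
        assert thr == 0.5

    def test_matches_exhaustive_oracle(self):
        rng = np.random.Generator(np.random.PCG64(123))
        for trial in range(30):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(1, 6))
            X = rng.integers(0, 5, size=(n, k)).astype(float)
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            rows = np.arange(n)
            ours = rf.best_split(X, y, rows, range(k), min_gain=0.0)
            oracle = brute_force_best_split(X, y, rows, range(k), min_gain=0.0)
            if oracle is None:
                assert ours is None
            else:
                assert ours is not None
                assert ours[2] == pytest.approx(oracle[2], abs=1e-12)


class TestCrossoverThreshold:
    def test_intercept(self):
        assert rf.crossover_threshold(0, 0) == 3705.0

    def test_direct_evaluation(self):
        assert rf.crossover_threshold(10000, 100) == pytest.approx(6466.0)

    def test_large_assay_scale(self):
        # 296,456 training compounds, all 179 descriptors per split
        assert rf.crossover_threshold(296456, 179) == pytest.approx(24719.8712)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rf.crossover_threshold(-1, 0)


class TestBootstrap:
    def test_size_range_and_determinism(self):
        a = rf.bootstrap_sample(5, _rng(0, "bootstrap", 1))
        b = rf.bootstrap_sample(5, _rng(0, "bootstrap", 1))
        assert a.shape == (5,)
        assert np.all((a >= 0) & (a < 5))
        np.testing.assert_array_equal(a, b)

    def test_distinct_fraction_matches_inclusion_probability(self):
        # E[fraction distinct] = 1 - (1 - 1/n)^n
        n = 50
        rng = _rng("bootstrap-stat")
        fracs = [len(set(rf.bootstrap_sample(n, rng).tolist())) / n for _ in range(10000)]
        expected = 1.0 - (1.0 - 1.0 / n) ** n
        assert np.mean(fracs) == pytest.approx(expected, abs=0.01)


class TestNodeFeatureSubset:
    def test_full_set_when_f_equals_total(self):
        np.testing.assert_array_equal(rf.node_feature_subset(7, 1, 10, 10), np.arange(10))

    def test_deterministic(self):
        a = rf.node_feature_subset(7, 13, 5, 179)
        b = rf.node_feature_subset(7, 13, 5, 179)
        np.testing.assert_array_equal(a, b)
        assert len(set(a.tolist())) == 5

    def test_siblings_rarely_collide(self):
        rng = np.random.Generator(np.random.PCG64(5))
        collisions = 0
        for _ in range(1000):
            seed = int(rng.integers(0, 2**31))
            path = int(rng.integers(1, 2**20))
            left = rf.node_feature_subset(seed, 2 * path, 14, 179)
            right = rf.node_feature_subset(seed, 2 * path + 1, 14, 179)
            collisions += int(np.array_equal(left, right))
        assert collisions < 10


def _embed(X2, y):
    """Embed a 2-feature toy problem into a 179-wide feature table."""
    mat = np.zeros((X2.shape[0], 179))
    mat[:, :2] = X2
    return rf.FeatureTable(matrix=mat, ids=[f"r{i}" for i in range(len(y))], labels=np.asarray(y))


class TestBuildTreeHybrid:
    def test_single_class_is_one_leaf(self):
        table = _embed(np.random.default_rng(0).normal(size=(10, 2)), np.ones(10, dtype=int))
        tree = rf.build_tree_hybrid(table, np.arange(10), rf.ForestParams(), tree_seed=1)
        assert len(tree.nodes) == 1
        assert tree.nodes[tree.root_id].kind == "leaf"
        assert tree.nodes[tree.root_id].label == rf.ACTIVE

    def test_axis_separable_training_accuracy(self):
        rng = np.random.Generator(np.random.PCG64(2))
        X2 = rng.normal(size=(40, 2))
        y = (X2[:, 0] > 0).astype(int)
        X2[:, 0] += np.where(y == 1, 0.5, -0.5)  # enforce a margin
        table = _embed(X2, y)
        params = rf.ForestParams(max_features=179)
        tree = rf.build_tree_hybrid(table, np.arange(40), params, tree_seed=9)
        preds = np.array([rf.predict_tree(tree, table.matrix[i]) for i in range(40)])
        assert (preds == y).all()

    def test_sample_conservation_and_tree_shape(self, assay_small):
        params = rf.ForestParams(max_features=14)
        tree = rf.build_tree_hybrid(assay_small, np.arange(assay_small.n), params, tree_seed=5)
        seen_as_child = set()
        for node in tree.nodes:
            if node.kind == "internal":
                left, right = tree.nodes[node.left_child], tree.nodes[node.right_child]
                assert left.n_samples + right.n_samples == node.n_samples
                assert 0 <= node.feature_index < 179
                for c in (node.left_child, node.right_child):
                    assert c not in seen_as_child  # single parent
                    seen_as_child.add(c)
            else:
                assert node.label in (rf.ACTIVE, rf.INACTIVE)
        assert tree.root_id not in seen_as_child
        assert seen_as_child | {tree.root_id} == {n.node_id for n in tree.nodes}

    @pytest.mark.parametrize("bfs", [0.0, "auto", 1e9])
    def test_construction_order_invariance(self, assay_small, bfs):
        params = rf.ForestParams(max_features=14, bfs_threshold=bfs)
        tree = rf.build_tree_hybrid(assay_small, np.arange(assay_small.n), params, tree_seed=11)
        grid = rf.generate_assay(rf.AssaySpec(n=60, effect_size=2.0, seed=77)).matrix
        preds = [rf.predict_tree(tree, grid[i]) for i in range(60)]
        ref_params = rf.ForestParams(max_features=14, bfs_threshold=0.0)
        ref = rf.build_tree_hybrid(assay_small, np.arange(assay_small.n), ref_params, tree_seed=11)
        assert preds == [rf.predict_tree(ref, grid[i]) for i in range(60)]

    def test_unlabelled_table_rejected(self, assay_small):
        table = rf.FeatureTable(matrix=assay_small.matrix, ids=assay_small.ids)
        with pytest.raises(ValueError):
            rf.build_tree_hybrid(table, np.arange(table.n), rf.ForestParams(), tree_seed=1)


class TestTrainForest:
    def test_single_tree_model_equals_tree(self, assay_small):
        model = rf.train_forest(assay_small, rf.ForestParams(n_trees=1, seed=5))
        labels, _ = rf.predict_forest(model, assay_small)
        tree_preds = np.array(
            [rf.predict_tree(model.trees[0], assay_small.matrix[i]) for i in range(assay_small.n)]
        )
        np.testing.assert_array_equal(labels, tree_preds)

    def test_same_seed_byte_identical_serialization(self, assay_small):
        params = rf.ForestParams(n_trees=3, seed=21)
        a = json.dumps(rf.train_forest(assay_small, params).to_dict(), sort_keys=True)
        b = json.dumps(rf.train_forest(assay_small, params).to_dict(), sort_keys=True)
        assert a == b

    def test_single_class_rejected(self):
        table = _embed(np.zeros((10, 2)), np.ones(10, dtype=int))
        with pytest.raises(ValueError):
            rf.train_forest(table, rf.ForestParams(n_trees=2))

    def test_oob_accuracy_on_separable_assay(self):
        table = rf.generate_assay(rf.AssaySpec(n=500, effect_size=2.0, seed=31))
        model = rf.train_forest(table, rf.ForestParams(n_trees=50, seed=8))
        oob = model.training_summary["oob_indices"]
        assert len(oob) == 50
        # aggregate out-of-bag majority vote per row
        votes = np.zeros((table.n, 2), dtype=int)
        for tree, idx in zip(model.trees, oob):
            if not idx:
                continue
            idx = np.asarray(idx)
            preds = [rf.predict_tree(tree, table.matrix[i]) for i in idx]
            for i, p in zip(idx, preds):
                votes[i, p] += 1
        covered = votes.sum(axis=1) > 0
        oob_pred = np.where(votes[covered, 1] >= votes[covered, 0], rf.ACTIVE, rf.INACTIVE)
        oob_acc = (oob_pred == table.labels[covered]).mean()
        assert oob_acc >= 0.9

    def test_params_validation(self):
        with pytest.raises(ValueError):
            rf.ForestParams(n_trees=0)
        with pytest.raises(ValueError):
            rf.ForestParams(gini_leaf_threshold=0.6)
        with pytest.raises(ValueError):
            rf.ForestParams(bfs_threshold=-1.0)
        with pytest.raises(ValueError):
            rf.ForestParams(bfs_threshold="sometimes")
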