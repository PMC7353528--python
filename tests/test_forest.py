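"""The regression forest: impurity arithmetic, split search, importance, CV."""

import numpy as np
import pytest

from sensefuse import forest
from sensefuse.forest import (
    DecisionNode, RandomForest, best_split, grow_tree, impurity_reduction,
    mae, make_folds, mse, node_impurity, ten_fold_cv,
)


class TestMetrics:
    @pytest.mark.parametrize("y,yhat,expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([0, 2], [1, 1], 1.0),
        ([3], [0], 9.0),
    ])
    def test_mse(self, y, yhat, expected):
        assert mse(y, yhat) == pytest.approx(expected)

    @pytest.mark.parametrize("y,yhat,expected", [
        ([1, 2], [1, 2], 0.0),
        ([0, 2], [1, 1], 1.0),
        ([-3, 3], [3, -3], 6.0),
    ])
    def test_mae(self, y, yhat, expected):
        assert mae(y, yhat) == pytest.approx(expected)

    @pytest.mark.parametrize("y,expected", [
        ([1, 1, 1], 0.0),
        ([0, 2], 1.0),
        ([-3, 3], 9.0),
    ])
    def test_node_impurity_is_variance(self, y, expected):
        assert node_impurity(y) == pytest.approx(expected)


def _leaf(w, imp, n=1, value=0.0):
    return DecisionNode(feature=-1, threshold=0.0, impurity=imp, weight=w,
                        n_samples=n, value=value)


class TestImpurityReduction:
    def test_pure_children_hand_case(self):
        # y = (0,0,2,2): parent impurity 1, both children pure
        node = DecisionNode(feature=0, threshold=2.5, impurity=1.0, weight=1.0,
                            n_samples=4, value=1.0,
                            left=_leaf(0.5, 0.0, 2), right=_leaf(0.5, 0.0, 2))
        assert impurity_reduction(node) == pytest.approx(1.0)

    def test_identical_child_distributions_give_zero(self):
        # split of y = (0,2,0,2) into two (0,2) halves
        node = DecisionNode(feature=0, threshold=0.5, impurity=1.0, weight=1.0,
                            n_samples=4, value=1.0,
                            left=_leaf(0.5, 1.0, 2), right=_leaf(0.5, 1.0, 2))
        assert impurity_reduction(node) == pytest.approx(0.0)

    def test_leaf_rejected(self):
        with pytest.raises(ValueError):
            impurity_reduction(_leaf(1.0, 0.0))

    def test_matches_direct_recomputation_on_random_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            X = rng.normal(size=(30, 4))
            y = rng.normal(size=30)
            tree = grow_tree(X, y)

            def check(node):
                if node.is_leaf:
                    return
                ir = impurity_reduction(node)
                direct = (node.weight * node.impurity
                          - node.left.weight * node.left.impurity
                          - node.right.weight * node.right.impurity)
                assert ir == pytest.approx(direct)
                assert ir >= -1e-12
                check(node.left)
                check(node.right)

            check(tree.root)


def _brute_force_best_split(X, y):
    """Exhaustive reference: every feature, every midpoint threshold."""
    n, p = X.shape
    parent = np.var(y)
    best = None  # (gain, feature, threshold)
    for f in range(p):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2
            left = y[X[:, f] <= thr]
            right = y[X[:, f] > thr]
            gain = n * parent - (left.size * np.var(left) + right.size * np.var(right))
            if best is None or gain > best[0]:
                best = (gain, f, thr)
    if best is None or best[0] <= 1e-12:
        return None
    return best


class TestBestSplit:
    def test_simple_separation(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.0, 0.0, 2.0, 2.0])
        split = best_split(X, y)
        assert split.feature == 0
        assert split.threshold == pytest.approx(2.5)
        assert split.ir == pytest.approx(1.0)

    def test_constant_response_yields_no_split(self):
        X = np.arange(8, dtype=float).reshape(-1, 1)
        assert best_split(X, np.full(8, 3.0)) is None

    def test_constant_feature_yields_no_split(self):
        X = np.ones((6, 1))
        assert best_split(X, np.arange(6, dtype=float)) is None

    def test_matches_brute_force_on_random_datasets(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            X = rng.normal(size=(20, 3))
            y = rng.normal(size=20)
            got = best_split(X, y)
            want = _brute_force_best_split(X, y)
            assert got is not None and want is not None
            assert got.feature == want[1]
            assert got.threshold == pytest.approx(want[2])
            assert got.ir * 20 == pytest.approx(want[0])

    def test_candidate_feature_restriction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 4))
        y = X[:, 2].copy()
        split = best_split(X, y, candidate_features=[0, 1])
        assert split.feature in (0, 1)


class TestGrowTree:
    def test_separable_data_zero_training_error(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1.0, 1.0, 5.0, 9.0])
        tree = grow_tree(X, y)
        np.testing.assert_allclose(tree.predict(X), y)

    def test_depth_cap_respected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        y = rng.normal(size=100)
        tree = grow_tree(X, y, max_depth=3)

        def depth(node, d=0):
            if node.is_leaf:
                return d
            return max(depth(node.left, d + 1), depth(node.right, d + 1))

        assert depth(tree.root) <= 3

    def test_telescoping_impurity_identity(self):
        # sum of IR over internal nodes = weighted root minus weighted leaves
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 4))
        y = rng.normal(size=60)
        tree = grow_tree(X, y)
        feats, irs = tree.impurity_reductions()
        leaves = tree.feature_arr < 0
        leaf_term = float(np.sum(tree.n_node_arr[leaves] * tree.impurity_arr[leaves])) / tree.n_total
        root_term = tree.impurity_arr[0] * tree.n_node_arr[0] / tree.n_total
        assert irs.sum() == pytest.approx(root_term - leaf_term, abs=1e-9)

    def test_matches_sklearn_tree_predictions(self):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(21)
        for _ in range(5):
            X = rng.normal(size=(40, 3))
            y = rng.normal(size=40)
            mine = grow_tree(X, y)
            ref = sklearn_tree.DecisionTreeRegressor(random_state=0).fit(X, y)
            np.testing.assert_allclose(mine.predict(X), ref.predict(X))

    def test_importance_matches_sklearn_single_tree(self):
        # depth-limited so no node is small enough to have exactly tied
        # split gains (ties resolve differently across implementations
        # without changing the fitted function)
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(22)
        X = rng.normal(size=(200, 5))
        y = X[:, 1] * 2 + X[:, 3] + rng.normal(0, 0.3, 200)
        mine = grow_tree(X, y, max_depth=4).feature_importance(5)
        ref = sklearn_tree.DecisionTreeRegressor(random_state=0, max_depth=4).fit(X, y)
        # small atol: the two implementations accumulate node variances in
        # different orders, which perturbs tiny importance shares
        np.testing.assert_allclose(mine, ref.feature_importances_, atol=5e-4)


class TestRandomForest:
    def test_default_has_30_trees(self):
        rng = np.random.default_rng(0)
        model = RandomForest(seed=1).fit(rng.normal(size=(40, 5)), rng.normal(size=40))
        assert model.n_trees == 30
        assert len(model.trees_) == 30

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(50, 4)), rng.normal(size=50)
        p1 = RandomForest(seed=9).fit(X, y).predict(X)
        p2 = RandomForest(seed=9).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_sample_training(self):
        model = RandomForest(n_trees=5, seed=0).fit(np.array([[1.0, 2.0]]), np.array([2.0]))
        assert all(t.n_nodes == 1 for t in model.trees_)
        assert model.predict(np.array([[9.0, 9.0]]))[0] == pytest.approx(2.0)

    def test_constant_response(self):
        rng = np.random.default_rng(0)
        model = RandomForest(seed=0).fit(rng.normal(size=(20, 3)), np.full(20, 2.0))
        assert model.predict(rng.normal(size=(5, 3))) == pytest.approx(np.full(5, 2.0))

    def test_prediction_is_tree_mean(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(30, 3)), rng.normal(size=30)
        model = RandomForest(n_trees=7, seed=4).fit(X, y)
        Q = rng.normal(size=(10, 3))
        by_hand = np.mean([t.predict(Q) for t in model.trees_], axis=0)
        np.testing.assert_allclose(model.predict(Q), by_hand)

    def test_prediction_within_training_range(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(50, 3)), rng.uniform(-3, 3, 50)
        model = RandomForest(seed=0).fit(X, y)
        preds = model.predict(rng.normal(size=(100, 3)) * 10)
        assert preds.min() >= y.min() and preds.max() <= y.max()

    def test_serialization_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        X, y = rng.normal(size=(30, 4)), rng.normal(size=30)
        model = RandomForest(n_trees=5, seed=1).fit(X, y)
        path = tmp_path / "forest.json"
        model.save(path)
        back = RandomForest.load(path)
        np.testing.assert_array_equal(model.predict(X), back.predict(X))
        np.testing.assert_allclose(model.feature_importance().importances,
                                   back.feature_importance().importances)


class TestFeatureImportance:
    def test_single_split_tree_concentrates_importance(self):
        X = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0], [0.0, 4.0]])
        y = np.array([0.0, 0.0, 2.0, 2.0])
        fi = grow_tree(X, y).feature_importance(2)
        np.testing.assert_allclose(fi, [0.0, 1.0])

    def test_forest_of_single_feature_splits(self):
        X = np.array([[0.0, v] for v in [1, 2, 3, 4, 1, 2, 3, 4]], dtype=float)
        y = np.array([0, 0, 2, 2, 0, 0, 2, 2], dtype=float)
        model = RandomForest(n_trees=10, max_features=None, seed=0).fit(X, y)
        rep = model.feature_importance()
        np.testing.assert_allclose(rep.importances, [0.0, 1.0])

    def test_sums_to_one_and_nonnegative(self):
        rng = np.random.default_rng(6)
        X, y = rng.normal(size=(60, 8)), rng.normal(size=60)
        rep = RandomForest(seed=2).fit(X, y).feature_importance()
        assert rep.importances.sum() == pytest.approx(1.0, abs=1e-9)
        assert (rep.importances >= 0).all()

    def test_signal_feature_recovered(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(200, 10))
        y = 3.0 * X[:, 7] + rng.normal(0, 0.2, 200)
        rep = RandomForest(seed=3).fit(X, y).feature_importance()
        assert rep.ranking()[0][0] == "f7"

    def test_unused_features_have_zero_importance(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
        y = np.array([0.0, 0.0, 2.0, 2.0])
        rep = RandomForest(n_trees=5, max_features=None, seed=0).fit(X, y).feature_importance()
        assert rep.importances[1] == 0.0


class TestCrossValidation:
    def test_folds_partition_with_near_equal_sizes(self):
        folds = make_folds(103, 10, seed=1)
        sizes = [f.size for f in folds]
        assert max(sizes) - min(sizes) <= 1
        allidx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(allidx, np.arange(103))

    def test_hundred_samples_make_ten_folds_of_ten(self):
        folds = make_folds(100, 10, seed=0)
        assert [f.size for f in folds] == [10] * 10

    def test_constant_response_zero_mae(self):
        rng = np.random.default_rng(0)
        res = ten_fold_cv(rng.normal(size=(40, 3)), np.full(40, 1.5), seed=2, n_trees=5)
        assert res.mean_mae == pytest.approx(0.0)

    def test_mean_equals_fold_mean_and_reproducible(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(50, 4)), rng.normal(size=50)
        r1 = ten_fold_cv(X, y, seed=7, n_trees=5)
        r2 = ten_fold_cv(X, y, seed=7, n_trees=5)
        assert r1.mean_mae == pytest.approx(np.mean(r1.fold_maes))
        assert r1.mean_mae == r2.mean_mae
        np.testing.assert_array_equal(np.concatenate(r1.folds), np.concatenate(r2.folds))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 10)


class TestSubsetExperiment:
    def test_five_groups_with_documented_widths(self):
        groups = forest.feature_subsets()
        assert list(groups) == ["sensors + emotions", "emotions only", "sensors only",
                                "GSR only", "pulse only"]
        assert [len(v) for v in groups.values()] == [44, 36, 8, 4, 4]

    def test_table_structure(self, small_features):
        table = forest.subset_experiment(small_features, seed=0, n_trees=5)
        assert list(table.index) == list(forest.feature_subsets())
        assert set(table.columns) == {"taste", "smell"}
        assert np.isfinite(table.to_numpy()).all()
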