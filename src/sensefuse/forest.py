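"""Regression random forest with impurity-based feature importance.

This is a from-scratch implementation of the acceptance predictor: an
ensemble of regression trees (30 by default) grown by exhaustive
MSE-impurity split search.  The pieces are exposed individually because
the importance bookkeeping is the point, not just the predictions:

* node impurity ``I_j`` is the variance of the node's responses, i.e. the
  mean squared error about the node mean;
* a split's impurity reduction is ``IR_j = w_j I_j - (w_l I_l + w_r I_r)``
  with weights ``w = n_node / n_total`` relative to the tree's training
  set;
* a feature's importance in a tree is its share of the tree's total
  impurity reduction, ``FI_k = sum_{j in N_k} IR_j / sum_{j in N} IR_j``,
  which sums to one; forest importance averages the per-tree shares.

Model quality is evaluated by ten-fold cross-validated mean absolute
error.  Hot loops (split search, tree growth, prediction) are compiled
with numba; trees are stored as flat arrays and can be materialized as a
:class:`DecisionNode` graph for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from numba import njit

from . import fusion

# ---------------------------------------------------------------------------
# error metrics and impurity


def mse(y: Iterable[float], y_pred: Iterable[float]) -> float:
    """Mean squared error, ``(1/n) * sum (y_i - yhat_i)^2``."""
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.size != y_pred.size or y.size == 0:
        raise ValueError("y and y_pred must be non-empty and of equal length")
    return float(np.mean((y - y_pred) ** 2))


def mae(y: Iterable[float], y_pred: Iterable[float]) -> float:
    """Mean absolute error, ``(1/n) * sum |y_i - yhat_i|``."""
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.size != y_pred.size or y.size == 0:
        raise ValueError("y and y_pred must be non-empty and of equal length")
    return float(np.mean(np.abs(y - y_pred)))


def node_impurity(y: Iterable[float]) -> float:
    """MSE of a node about its own mean — the variance of the responses."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("node is empty")
    return mse(y, np.full_like(y, y.mean()))


# ---------------------------------------------------------------------------
# compiled kernels


@njit(cache=True)
def _scan_best_split(X, y, idx, start, end, feats, min_samples_leaf):
    """Exhaustive split search over *feats* for the node idx[start:end].

    Candidate thresholds are midpoints between consecutive distinct sorted
    values.  Returns (feature, threshold, gain) where gain is
    ``m*I_parent - (m_l*I_l + m_r*I_r)`` (impurity reduction times the
    tree's total sample count); feature is -1 when no valid split exists.
    Features are scanned in the given (ascending) order and thresholds in
    ascending order with strict improvement, so ties resolve to the lowest
    feature index, then the lowest threshold.
    """
    m = end - start
    s = 0.0
    ss = 0.0
    for i in range(start, end):
        yi = y[idx[i]]
        s += yi
        ss += yi * yi
    imp_parent = ss / m - (s / m) ** 2
    if imp_parent < 0.0:
        imp_parent = 0.0
    best_f = -1
    best_thr = 0.0
    best_gain = 0.0
    v = np.empty(m, dtype=np.float64)
    yv = np.empty(m, dtype=np.float64)
    for fpos in range(feats.size):
        f = feats[fpos]
        for i in range(m):
            v[i] = X[idx[start + i], f]
        order = np.argsort(v)
        sl = 0.0
        ssl = 0.0
        for i in range(m):
            yv[i] = y[idx[start + order[i]]]
        for i in range(m - 1):
            yi = yv[i]
            sl += yi
            ssl += yi * yi
            if v[order[i + 1]] <= v[order[i]]:
                continue
            ml = i + 1
            mr = m - ml
            if ml < min_samples_leaf or mr < min_samples_leaf:
                continue
            imp_l = ssl / ml - (sl / ml) ** 2
            sr = s - sl
            ssr = ss - ssl
            imp_r = ssr / mr - (sr / mr) ** 2
            if imp_l < 0.0:
                imp_l = 0.0
            if imp_r < 0.0:
                imp_r = 0.0
            gain = m * imp_parent - (ml * imp_l + mr * imp_r)
            if gain > best_gain:
                best_gain = gain
                best_f = f
                best_thr = (v[order[i]] + v[order[i + 1]]) / 2.0
    return best_f, best_thr, best_gain


@njit(cache=True)
def _grow(X, y, idx, feats, min_samples_split, min_samples_leaf, max_depth,
          feature, threshold, left, right, value, impurity, n_node):
    """Grow one tree depth-first with an explicit stack.

    idx is partitioned in place; node attributes are written into the
    preallocated flat arrays.  Returns the number of nodes used.
    """
    n_total = idx.size
    cap = feature.size
    stack_node = np.empty(cap, dtype=np.int64)
    stack_start = np.empty(cap, dtype=np.int64)
    stack_end = np.empty(cap, dtype=np.int64)
    stack_depth = np.empty(cap, dtype=np.int64)
    top = 0
    stack_node[0] = 0
    stack_start[0] = 0
    stack_end[0] = n_total
    stack_depth[0] = 0
    top = 1
    n_nodes = 1
    while top > 0:
        top -= 1
        node = stack_node[top]
        start = stack_start[top]
        end = stack_end[top]
        depth = stack_depth[top]
        m = end - start
        s = 0.0
        ss = 0.0
        for i in range(start, end):
            yi = y[idx[i]]
            s += yi
            ss += yi * yi
        mean = s / m
        imp = ss / m - mean * mean
        if imp < 0.0:
            imp = 0.0
        value[node] = mean
        impurity[node] = imp
        n_node[node] = m
        feature[node] = -1
        left[node] = -1
        right[node] = -1
        if m < min_samples_split or imp <= 1e-15:
            continue
        if max_depth >= 0 and depth >= max_depth:
            continue
        f, thr, gain = _scan_best_split(X, y, idx, start, end, feats, min_samples_leaf)
        if f < 0 or gain <= 1e-12:
            continue
        # partition idx[start:end] on X[., f] <= thr
        i = start
        j = end - 1
        while i <= j:
            if X[idx[i], f] <= thr:
                i += 1
            else:
                tmp = idx[i]
                idx[i] = idx[j]
                idx[j] = tmp
                j -= 1
        mid = i
        if mid == start or mid == end:  # numerically degenerate partition
            continue
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        feature[node] = f
        threshold[node] = thr
        left[node] = lid
        right[node] = rid
        stack_node[top] = lid
        stack_start[top] = start
        stack_end[top] = mid
        stack_depth[top] = depth + 1
        top += 1
        stack_node[top] = rid
        stack_start[top] = mid
        stack_end[top] = end
        stack_depth[top] = depth + 1
        top += 1
    return n_nodes


@njit(cache=True)
def _predict_tree(Xq, feature, threshold, left, right, value, out):
    for i in range(Xq.shape[0]):
        node = 0
        while feature[node] >= 0:
            if Xq[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] += value[node]


# ---------------------------------------------------------------------------
# node-level API


@dataclass
class DecisionNode:
    """One tree node with the bookkeeping needed for importance.

    ``weight`` is the node's sample fraction relative to the tree's full
    training set; leaves carry the node mean as ``value`` and no children.
    """

    feature: int  # -1 for leaves
    threshold: float
    impurity: float
    weight: float
    n_samples: int
    value: float
    left: "DecisionNode | None" = None
    right: "DecisionNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


class BestSplit(NamedTuple):
    feature: int
    threshold: float
    ir: float


def impurity_reduction(node: DecisionNode) -> float:
    """``IR_j = w_j I_j - (w_left I_left + w_right I_right)`` for an internal node."""
    if node.is_leaf:
        raise ValueError("impurity reduction is defined for internal nodes only")
    return (node.weight * node.impurity
            - (node.left.weight * node.left.impurity + node.right.weight * node.right.impurity))


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    candidate_features: Sequence[int] | None = None,
    total_samples: int | None = None,
    min_samples_leaf: int = 1,
) -> BestSplit | None:
    """Exhaustive best split of one node's data; None when no split helps.

    Thresholds are midpoints between consecutive distinct sorted values of
    each candidate feature; the returned split maximizes the impurity
    reduction with weights taken relative to *total_samples* (defaults to
    the node's own size, i.e. the node is treated as a root).  Ties break
    to the lowest feature index, then the lowest threshold.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with one response per row")
    n = y.size
    if n < 2:
        return None
    feats = (np.arange(X.shape[1]) if candidate_features is None
             else np.asarray(sorted(candidate_features), dtype=np.int64))
    idx = np.arange(n, dtype=np.int64)
    f, thr, gain = _scan_best_split(X, y, idx, 0, n, feats, min_samples_leaf)
    if f < 0 or gain <= 1e-12:
        return None
    n_total = n if total_samples is None else total_samples
    return BestSplit(int(f), float(thr), float(gain / n_total))


# ---------------------------------------------------------------------------
# trees and forest


class RegressionTree:
    """A single regression tree stored as flat arrays."""

    def __init__(self, feature, threshold, left, right, value, impurity, n_node, n_total, feature_subset):
        self.feature_arr = feature
        self.threshold_arr = threshold
        self.left_arr = left
        self.right_arr = right
        self.value_arr = value
        self.impurity_arr = impurity
        self.n_node_arr = n_node
        self.n_total = n_total
        self.feature_subset = feature_subset

    @property
    def n_nodes(self) -> int:
        return self.feature_arr.size

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
        out = np.zeros(X.shape[0])
        _predict_tree(X, self.feature_arr, self.threshold_arr, self.left_arr,
                      self.right_arr, self.value_arr, out)
        return out

    @property
    def root(self) -> DecisionNode:
        """Materialize the array representation as a DecisionNode graph."""
        def build(i: int) -> DecisionNode:
            node = DecisionNode(
                feature=int(self.feature_arr[i]),
                threshold=float(self.threshold_arr[i]),
                impurity=float(self.impurity_arr[i]),
                weight=float(self.n_node_arr[i] / self.n_total),
                n_samples=int(self.n_node_arr[i]),
                value=float(self.value_arr[i]),
            )
            if self.feature_arr[i] >= 0:
                node.left = build(int(self.left_arr[i]))
                node.right = build(int(self.right_arr[i]))
            return node
        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, self.n_nodes + 100))
        try:
            return build(0)
        finally:
            sys.setrecursionlimit(old)

    def impurity_reductions(self) -> tuple[np.ndarray, np.ndarray]:
        """(feature index, IR) for every internal node, vectorized."""
        internal = self.feature_arr >= 0
        if not internal.any():
            return np.empty(0, dtype=np.int64), np.empty(0)
        l = self.left_arr[internal]
        r = self.right_arr[internal]
        ir = (self.n_node_arr[internal] * self.impurity_arr[internal]
              - self.n_node_arr[l] * self.impurity_arr[l]
              - self.n_node_arr[r] * self.impurity_arr[r]) / self.n_total
        return self.feature_arr[internal], ir

    def feature_importance(self, n_features: int) -> np.ndarray:
        """Per-tree FI: each feature's share of total impurity reduction."""
        feats, ir = self.impurity_reductions()
        fi = np.zeros(n_features)
        if ir.size == 0:
            return fi
        total = ir.sum()
        if total <= 0:
            return fi
        np.add.at(fi, feats, ir)
        return fi / total


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_depth: int | None = None,
    min_samples_split: int = 2,
    min_samples_leaf: int = 1,
    sample_indices: np.ndarray | None = None,
    feature_indices: np.ndarray | None = None,
) -> RegressionTree:
    """Grow one tree by recursive exhaustive split search.

    Splitting stops at pure nodes, nodes below ``min_samples_split``, the
    optional depth cap, or when no candidate split reduces impurity;
    leaves predict the mean response of their samples.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.size or y.size == 0:
        raise ValueError("X must be (n, p) with one response per row, n >= 1")
    idx = (np.arange(y.size, dtype=np.int64) if sample_indices is None
           else np.asarray(sample_indices, dtype=np.int64).copy())
    feats = (np.arange(X.shape[1], dtype=np.int64) if feature_indices is None
             else np.asarray(sorted(feature_indices), dtype=np.int64))
    n = idx.size
    cap = 2 * n + 1
    feature = np.empty(cap, dtype=np.int64)
    threshold = np.zeros(cap)
    left = np.empty(cap, dtype=np.int64)
    right = np.empty(cap, dtype=np.int64)
    value = np.zeros(cap)
    impurity = np.zeros(cap)
    n_node = np.zeros(cap, dtype=np.int64)
    depth_cap = -1 if max_depth is None else int(max_depth)
    n_nodes = _grow(X, y, idx, feats, min_samples_split, min_samples_leaf, depth_cap,
                    feature, threshold, left, right, value, impurity, n_node)
    return RegressionTree(
        feature[:n_nodes].copy(), threshold[:n_nodes].copy(), left[:n_nodes].copy(),
        right[:n_nodes].copy(), value[:n_nodes].copy(), impurity[:n_nodes].copy(),
        n_node[:n_nodes].copy(), n, feats,
    )


@dataclass(frozen=True)
class ImportanceReport:
    """Per-feature importance shares (non-negative, summing to one)."""

    importances: np.ndarray
    names: tuple[str, ...]

    def ranking(self) -> list[tuple[str, float]]:
        """Features by descending importance; ties break by name."""
        order = sorted(range(len(self.names)), key=lambda i: (-self.importances[i], self.names[i]))
        return [(self.names[i], float(self.importances[i])) for i in order]

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        return self.ranking()[:k]

    def as_series(self) -> pd.Series:
        return pd.Series(self.importances, index=list(self.names), name="importance")


class RandomForest:
    """Bagged regression trees with per-tree random feature subsets.

    Each of ``n_trees`` (default 30) trees is grown on a bootstrap sample
    of the rows and a random feature subset of size ``ceil(p / 3)`` (the
    regression convention; configurable via ``max_features``).  Prediction
    averages the trees; importance averages the per-tree normalized
    impurity-reduction shares.
    """

    def __init__(
        self,
        n_trees: int = 30,
        max_features: int | str | None = "third",
        bootstrap: bool = True,
        max_depth: int | None = None,
        min_samples_split: int = 2,
        min_samples_leaf: int = 1,
        seed: int | None = None,
    ):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed
        self.trees_: list[RegressionTree] = []
        self.feature_names_: tuple[str, ...] | None = None
        self.n_features_: int | None = None
        self.y_range_: tuple[float, float] | None = None

    def _n_candidate_features(self, p: int) -> int:
        mf = self.max_features
        if mf is None:
            return p
        if mf == "third":
            return max(1, int(np.ceil(p / 3)))
        k = int(mf)
        if not 1 <= k <= p:
            raise ValueError(f"max_features must be in [1, {p}], got {k}")
        return k

    def fit(self, X: np.ndarray, y: np.ndarray, feature_names: Sequence[str] | None = None) -> "RandomForest":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 2 or X.shape[0] != y.size or y.size == 0:
            raise ValueError("X must be (n, p) with one response per row, n >= 1")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("training matrix must not contain missing values")
        n, p = X.shape
        if feature_names is not None and len(feature_names) != p:
            raise ValueError("feature_names length must equal the number of columns")
        self.feature_names_ = tuple(feature_names) if feature_names is not None else tuple(
            f"f{i}" for i in range(p))
        self.n_features_ = p
        self.y_range_ = (float(y.min()), float(y.max()))
        rng = np.random.default_rng(self.seed)
        k = self._n_candidate_features(p)
        self.trees_ = []
        for _ in range(self.n_trees):
            rows = rng.integers(0, n, size=n) if self.bootstrap else np.arange(n)
            feats = np.sort(rng.choice(p, size=k, replace=False))
            self.trees_.append(grow_tree(
                X, y,
                max_depth=self.max_depth,
                min_samples_split=self.min_samples_split,
                min_samples_leaf=self.min_samples_leaf,
                sample_indices=rows.astype(np.int64),
                feature_indices=feats,
            ))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.trees_:
            raise RuntimeError("forest is not fitted")
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
        out = np.zeros(X.shape[0])
        for tree in self.trees_:
            _predict_tree(X, tree.feature_arr, tree.threshold_arr, tree.left_arr,
                          tree.right_arr, tree.value_arr, out)
        return out / len(self.trees_)

    def to_dict(self) -> dict:
        """Portable JSON-able serialization of a fitted forest."""
        if not self.trees_:
            raise RuntimeError("forest is not fitted")
        return {
            "format": "sensefuse-forest-v1",
            "params": {
                "n_trees": self.n_trees, "max_features": self.max_features,
                "bootstrap": self.bootstrap, "max_depth": self.max_depth,
                "min_samples_split": self.min_samples_split,
                "min_samples_leaf": self.min_samples_leaf, "seed": self.seed,
            },
            "feature_names": list(self.feature_names_),
            "y_range": list(self.y_range_),
            "trees": [
                {
                    "feature": t.feature_arr.tolist(), "threshold": t.threshold_arr.tolist(),
                    "left": t.left_arr.tolist(), "right": t.right_arr.tolist(),
                    "value": t.value_arr.tolist(), "impurity": t.impurity_arr.tolist(),
                    "n_node": t.n_node_arr.tolist(), "n_total": t.n_total,
                    "feature_subset": t.feature_subset.tolist(),
                }
                for t in self.trees_
            ],
        }

    def save(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, data: dict) -> "RandomForest":
        if data.get("format") != "sensefuse-forest-v1":
            raise ValueError("unrecognized forest serialization format")
        model = cls(**data["params"])
        model.feature_names_ = tuple(data["feature_names"])
        model.n_features_ = len(model.feature_names_)
        model.y_range_ = tuple(data["y_range"])
        model.trees_ = [
            RegressionTree(
                np.asarray(t["feature"], dtype=np.int64), np.asarray(t["threshold"]),
                np.asarray(t["left"], dtype=np.int64), np.asarray(t["right"], dtype=np.int64),
                np.asarray(t["value"]), np.asarray(t["impurity"]),
                np.asarray(t["n_node"], dtype=np.int64), int(t["n_total"]),
                np.asarray(t["feature_subset"], dtype=np.int64),
            )
            for t in data["trees"]
        ]
        return model

    @classmethod
    def load(cls, path) -> "RandomForest":
        import json
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def feature_importance(self) -> ImportanceReport:
        """Mean over trees of the per-tree normalized importance shares.

        Trees without a single split carry no importance information and
        are excluded from the average, so the report always sums to one
        whenever at least one tree split.
        """
        if not self.trees_:
            raise RuntimeError("forest is not fitted")
        per_tree = [t.feature_importance(self.n_features_) for t in self.trees_]
        informative = [fi for fi in per_tree if fi.sum() > 0]
        if not informative:
            fi = np.zeros(self.n_features_)
        else:
            fi = np.mean(informative, axis=0)
        return ImportanceReport(fi, self.feature_names_)


# ---------------------------------------------------------------------------
# cross-validation and the feature-subset experiment


@dataclass(frozen=True)
class CVResult:
    folds: tuple[np.ndarray, ...]
    fold_maes: np.ndarray
    mean_mae: float


def make_folds(n: int, n_folds: int, seed: int | None = None) -> tuple[np.ndarray, ...]:
    """Random partition of range(n) into n_folds blocks of near-equal size."""
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples for {n_folds}-fold CV, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return tuple(np.sort(block) for block in np.array_split(perm, n_folds))


def ten_fold_cv(
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = None,
    n_folds: int = 10,
    folds: tuple[np.ndarray, ...] | None = None,
    feature_names: Sequence[str] | None = None,
    **forest_params,
) -> CVResult:
    """K-fold (default ten) cross-validated MAE of the forest.

    The data are randomly partitioned into blocks; the model is fitted
    once per block on the remaining blocks and scored on the held-out one;
    the reported value is the mean of the per-fold MAEs.  A precomputed
    partition can be passed via *folds* so that different feature subsets
    are compared on identical splits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if folds is None:
        folds = make_folds(y.size, n_folds, seed)
    fold_maes = []
    for i, test_idx in enumerate(folds):
        mask = np.ones(y.size, dtype=bool)
        mask[test_idx] = False
        model = RandomForest(seed=None if seed is None else seed + 1000 * (i + 1), **forest_params)
        model.fit(X[mask], y[mask], feature_names=feature_names)
        fold_maes.append(mae(y[test_idx], model.predict(X[test_idx])))
    fold_maes = np.asarray(fold_maes)
    return CVResult(tuple(folds), fold_maes, float(fold_maes.mean()))


def feature_subsets(subset_labels: Sequence[str] = fusion.DEFAULT_NINE) -> dict[str, tuple[str, ...]]:
    """The five benchmark feature groups for the subset experiment."""
    emotions = fusion.emotion_feature_names(subset_labels)
    gsr = fusion.sensor_feature_names(("gsr",))
    pulse = fusion.sensor_feature_names(("pulse",))
    return {
        "sensors + emotions": (*emotions, *gsr, *pulse),
        "emotions only": emotions,
        "sensors only": (*gsr, *pulse),
        "GSR only": gsr,
        "pulse only": pulse,
    }


def subset_experiment(
    features: pd.DataFrame,
    seed: int | None = None,
    n_folds: int = 10,
    subset_labels: Sequence[str] = fusion.DEFAULT_NINE,
    **forest_params,
) -> pd.DataFrame:
    """Cross-validated MAE per feature group and modality.

    Runs ten-fold CV of the forest on each of the five feature groups
    (all 44 features; the 36 emotion features; the 8 sensor features; GSR
    alone; pulse alone), separately for each modality present in the
    feature matrix.  One fold partition per (seed, modality) is reused
    across groups so the comparison is split-for-split fair.  Returns a
    table with one row per group and one MAE column per modality.
    """
    groups = feature_subsets(subset_labels)
    modalities = list(dict.fromkeys(features["modality"])) if "modality" in features else ["all"]
    out: dict[str, list[float]] = {name: [] for name in groups}
    for modality in modalities:
        sub = features if modality == "all" else features[features["modality"] == modality]
        y = sub[fusion.TARGET_COLUMN].to_numpy(dtype=float)
        folds = make_folds(y.size, n_folds, seed)
        for name, cols in groups.items():
            X = sub[list(cols)].to_numpy(dtype=float)
            res = ten_fold_cv(X, y, seed=seed, folds=folds, feature_names=cols, **forest_params)
            out[name].append(res.mean_mae)
    return pd.DataFrame(out, index=modalities).T.rename_axis("data")
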