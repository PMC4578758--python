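"""Depth-capped binary CART trees with case weights.

These are the base learners of every boosting algorithm in the package:
classification trees (weighted Gini) for the AdaBoost family and
regression trees (weighted squared error) inside gradient and logit
boosting.  Only the depth cap regularizes: ``min_samples_split=2``,
``min_samples_leaf=1`` and no pruning, so a depth-5 tree can shatter a
small sample — which is exactly the overfitting regime the boosting
comparisons probe.

Split search is delegated to scikit-learn's optimized CART implementation
(midpoint thresholds, ``x_j <= t`` routed left, deterministic with a fixed
``random_state``); the fitted tree is then extracted into a plain-array
:class:`TreeModel` so prediction and JSON round-trips are self-contained.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .datasets import LabeledDataset

#: Sentinel used for the child indices and split fields of leaf nodes.
LEAF = -1


@dataclass
class TreeConfig:
    """Stopping rules of the base trees.

    ``max_depth=1`` is a decision stump (CART(1)); ``max_depth=5`` is the
    CART(5) learner used throughout the benchmarks.
    """

    max_depth: int = 5
    min_samples_split: int = 2
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.max_depth <= 32:
            raise ValueError("max_depth must lie in 1..32")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


@dataclass
class TreeModel:
    """A fitted binary tree as flat node arrays.

    ``children_left[i] == LEAF`` marks node ``i`` as a leaf; its prediction
    is ``value[i]`` (a class label in {1, 2} for classification trees, a
    real update for regression trees).  Internal nodes route
    ``x[feature[i]] <= threshold[i]`` to the left child.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray
    kind: str = "classification"  # or "regression"
    max_depth: int = field(default=0)

    def __post_init__(self) -> None:
        self.children_left = np.asarray(self.children_left, dtype=np.int64)
        self.children_right = np.asarray(self.children_right, dtype=np.int64)
        self.feature = np.asarray(self.feature, dtype=np.int64)
        self.threshold = np.asarray(self.threshold, dtype=np.float64)
        self.value = np.asarray(self.value, dtype=np.float64)

    @property
    def n_nodes(self) -> int:
        return self.children_left.shape[0]

    @property
    def is_leaf(self) -> np.ndarray:
        return self.children_left == LEAF

    @property
    def n_leaves(self) -> int:
        return int(self.is_leaf.sum())

    @property
    def n_variables_used(self) -> int:
        """Distinct split variables; at most 2^depth - 1."""
        return int(np.unique(self.feature[~self.is_leaf]).size)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index reached by each row of ``X`` (root-to-leaf routing)."""
        X = _check_matrix(X, self)
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = ~self.is_leaf[node]
        while active.any():
            idx = np.flatnonzero(active)
            cur = node[idx]
            go_left = X[idx, self.feature[cur]] <= self.threshold[cur]
            node[idx] = np.where(go_left, self.children_left[cur],
                                 self.children_right[cur])
            active = ~self.is_leaf[node]
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Leaf values reached by each row (labels or real updates)."""
        out = self.value[self.apply(X)]
        if self.kind == "classification":
            return out.astype(np.int64)
        return out

    # -- JSON serialization -------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("children_left", "children_right", "feature",
                  "threshold", "value"):
            d[k] = np.asarray(d[k]).tolist()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "TreeModel":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "TreeModel":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_sklearn(cls, est, kind: str) -> "TreeModel":
        """Extract the node arrays of a fitted sklearn tree."""
        t = est.tree_
        if kind == "classification":
            # weighted class counts -> majority label; np.argmax takes the
            # first maximum, i.e. ties resolve toward the smaller label.
            counts = t.value[:, 0, :] * t.weighted_n_node_samples[:, None]
            value = est.classes_[np.argmax(counts, axis=1)].astype(float)
        else:
            value = t.value[:, 0, 0].copy()
        return cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            value=value,
            kind=kind,
            max_depth=int(t.max_depth),
        )


def _check_matrix(X: np.ndarray, tree: TreeModel) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    internal = ~tree.is_leaf
    if internal.any() and X.shape[1] <= tree.feature[internal].max():
        raise ValueError("X has fewer columns than the tree's split "
                         "variables require")
    return X


def _check_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (n,):
        raise ValueError("weights must have one entry per sample")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    return w


def fit_classification_tree(data: LabeledDataset, weights=None,
                            config: TreeConfig | None = None,
                            random_state: int = 0) -> TreeModel:
    """Greedy weighted-Gini classification tree with a hard depth cap.

    A one-class input degenerates to a single leaf predicting the present
    class.  Leaf labels are the weighted majority class; label ties break
    toward class 1.
    """
    config = config or TreeConfig()
    w = _check_weights(weights, data.n_samples)
    est = DecisionTreeClassifier(
        criterion="gini",
        max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        min_samples_leaf=config.min_samples_leaf,
        random_state=random_state,
    )
    est.fit(data.X, data.y, sample_weight=w)
    return TreeModel.from_sklearn(est, "classification")


def fit_regression_tree(X: np.ndarray, targets: np.ndarray, weights=None,
                        config: TreeConfig | None = None,
                        random_state: int = 0) -> TreeModel:
    """Weighted least-squares regression tree; leaf value = weighted mean.

    Boosting-specific leaf transforms (Newton steps, half-steps) are the
    caller's responsibility.
    """
    config = config or TreeConfig()
    X = np.asarray(X, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if not np.isfinite(targets).all():
        raise ValueError("targets must be finite")
    w = _check_weights(weights, X.shape[0])
    est = DecisionTreeRegressor(
        criterion="squared_error",
        max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        min_samples_leaf=config.min_samples_leaf,
        random_state=random_state,
    )
    est.fit(X, targets, sample_weight=w)
    return TreeModel.from_sklearn(est, "regression")


def predict_tree(tree: TreeModel, X: np.ndarray) -> np.ndarray:
    """Route each row of ``X`` to a leaf and return the leaf values."""
    return tree.predict(X)
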