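"""From-scratch decision tree, random forest, and nearest-neighbor classifiers.

The tree learner is a plain CART-style binary tree with entropy
(information-gain) splits at midpoints of sorted distinct feature values.
It records, per node, the sample count and the information gain of the
split — the quantities the Monte Carlo feature-selection score is built
from — which is why the tree is implemented here rather than delegated to
a library whose internals do not expose them in the required form.

Splitting continues while a node is impure and a valid split exists
(children at least ``min_leaf`` rows); zero-gain splits are allowed on
impure nodes, as in standard CART, so that parity-style concepts (XOR)
are learnable and any consistent dataset is fitted to training accuracy
1.0 at ``min_leaf=1``.

The forest draws, per tree, a bootstrap sample of the rows and, per
split, ``m`` candidate features (default ``floor(log2(M)) + 1``).  The
forest vote fraction for the positive class is the prediction score; a
0.5 tie votes positive, which favors recall on the minority interacting
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .dataset_io import FeatureTable
from .errors import ValidationError
from .evaluation import Predictor, ScoredPredictions


def _entropy(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binary entropy in bits of ``pos`` positives among ``n`` samples (vectorized)."""
    n = np.asarray(n, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, pos / np.maximum(n, 1), 0.0)
        h = -(np.where(p > 0, p * np.log2(p), 0.0) + np.where(p < 1, (1 - p) * np.log2(1 - p), 0.0))
    return h


@dataclass
class DecisionTree:
    """Array-of-nodes binary classification tree.

    ``feature[i] == -1`` marks a leaf.  Children always have a larger
    index than their parent, so a single forward pass routes samples.
    ``gain`` holds the information gain of each internal node's split and
    ``n_samples``/``counts`` the samples reaching the node — consumed by
    the Monte Carlo feature-importance score.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    n_samples: np.ndarray
    counts: np.ndarray  # (n_nodes, 2) class counts
    gain: np.ndarray
    n_features_in: int
    wacc: float | None = None  # out-of-bag balanced accuracy, set by ensemble code

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def n_internal(self) -> int:
        return int((self.feature >= 0).sum())

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in:
            raise ValidationError(
                f"tree was fitted on {self.n_features_in} features, got {X.shape[1]}"
            )
        assign = np.zeros(len(X), dtype=np.int32)
        for i in range(self.n_nodes):
            if self.feature[i] < 0:
                continue
            at = np.flatnonzero(assign == i)
            if not at.size:
                continue
            go_left = X[at, self.feature[i]] <= self.threshold[i]
            assign[at] = np.where(go_left, self.left[i], self.right[i])
        return assign

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard votes; a tied leaf votes positive."""
        leaf = self.apply(X)
        return (self.counts[leaf, 1] >= self.counts[leaf, 0]).astype(np.int8)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        leaf = self.apply(X)
        c = self.counts[leaf].astype(np.float64)
        return c[:, 1] / c.sum(axis=1)


class _TreeBuilder:
    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        allowed: np.ndarray,
        min_leaf: int,
        rng: np.random.Generator | None,
        m: int | None,
    ):
        self.X, self.y = X, y
        self.allowed = allowed
        self.min_leaf = min_leaf
        self.rng = rng
        self.m = m
        self.nodes: list[list] = []  # feature, threshold, left, right, n, pos, gain

    def build(self, idx: np.ndarray) -> int:
        n = len(idx)
        pos = int(self.y[idx].sum())
        node = [-1, np.nan, -1, -1, n, pos, 0.0]
        node_id = len(self.nodes)
        self.nodes.append(node)
        if pos == 0 or pos == n or n < 2 * self.min_leaf:
            return node_id
        split = self._best_split(idx)
        if split is None:
            return node_id
        f, thr, g = split
        mask = self.X[idx, f] <= thr
        node[0], node[1], node[6] = f, thr, g
        node[2] = self.build(idx[mask])
        node[3] = self.build(idx[~mask])
        return node_id

    def _candidates(self) -> np.ndarray:
        if self.m is None or self.m >= len(self.allowed):
            return self.allowed
        draw = self.rng.choice(len(self.allowed), size=self.m, replace=False)
        return self.allowed[np.sort(draw)]

    def _best_split(self, idx: np.ndarray):
        best = self._search(idx, self._candidates())
        if best is None and self.m is not None and self.m < len(self.allowed):
            # none of the drawn candidates admits a valid split; widen the search
            best = self._search(idx, self.allowed)
        return best

    def _search(self, idx: np.ndarray, candidates: np.ndarray):
        n = len(idx)
        yi = self.y[idx].astype(np.float64)
        total_pos = yi.sum()
        parent_h = _entropy(np.array(total_pos), np.array(float(n)))
        best_gain, best = -np.inf, None
        for f in candidates:
            v = self.X[idx, f]
            order = np.argsort(v, kind="stable")
            vs, ys = v[order], yi[order]
            # split positions i: left = first i rows; need distinct boundary values
            i = np.arange(self.min_leaf, n - self.min_leaf + 1)
            valid = vs[i - 1] < vs[i]
            if not valid.any():
                continue
            i = i[valid]
            left_pos = np.cumsum(ys)[i - 1]
            left_n = i.astype(np.float64)
            right_pos = total_pos - left_pos
            right_n = n - left_n
            gain = parent_h - (
                left_n / n * _entropy(left_pos, left_n)
                + right_n / n * _entropy(right_pos, right_n)
            )
            j = int(np.argmax(gain))
            if gain[j] > best_gain + 1e-12:
                best_gain = float(gain[j])
                thr = float((vs[i[j] - 1] + vs[i[j]]) / 2)
                best = (int(f), thr, max(best_gain, 0.0))
        return best

    def finish(self) -> DecisionTree:
        counts = np.array(
            [[n[4] - n[5], n[5]] for n in self.nodes], dtype=np.int64
        )
        return DecisionTree(
            feature=np.array([n[0] for n in self.nodes], dtype=np.int32),
            threshold=np.array([n[1] for n in self.nodes], dtype=np.float64),
            left=np.array([n[2] for n in self.nodes], dtype=np.int32),
            right=np.array([n[3] for n in self.nodes], dtype=np.int32),
            n_samples=np.array([n[4] for n in self.nodes], dtype=np.int64),
            counts=counts,
            gain=np.array([n[6] for n in self.nodes], dtype=np.float64),
            n_features_in=self.X.shape[1],
        )


def fit_tree(
    table: FeatureTable,
    allowed_features: Sequence[int] | None = None,
    min_leaf: int = 2,
    seed: int = 0,
    feature_subsample: int | None = None,
) -> DecisionTree:
    """Fit a plain decision tree.

    ``allowed_features`` restricts the columns the tree may split on (all
    by default).  With ``feature_subsample=m``, each split considers a
    fresh random draw of ``m`` of the allowed features (forest mode).
    """
    return fit_tree_arrays(
        table.X, table.y, allowed_features, min_leaf, seed, feature_subsample
    )


def fit_tree_arrays(
    X: np.ndarray,
    y: np.ndarray,
    allowed_features: Sequence[int] | None = None,
    min_leaf: int = 2,
    seed: int | np.random.Generator = 0,
    feature_subsample: int | None = None,
) -> DecisionTree:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.size == 0:
        raise ValidationError("cannot fit a tree on an empty table")
    if min_leaf < 1:
        raise ValidationError("min_leaf must be >= 1")
    allowed = (
        np.arange(X.shape[1], dtype=np.int64)
        if allowed_features is None
        else np.asarray(sorted(allowed_features), dtype=np.int64)
    )
    if len(allowed) == 0 or allowed.min() < 0 or allowed.max() >= X.shape[1]:
        raise ValidationError("allowed_features out of range")
    if feature_subsample is not None and not 1 <= feature_subsample:
        raise ValidationError("feature_subsample must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    builder = _TreeBuilder(X, y, allowed, min_leaf, rng, feature_subsample)
    builder.build(np.arange(len(X)))
    return builder.finish()


def default_feature_subsample(n_features: int) -> int:
    """The conventional per-split candidate count floor(log2(M)) + 1."""
    return int(np.floor(np.log2(n_features))) + 1


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 100
    m: int | None = None  # features per split; default floor(log2 M) + 1
    seed: int = 0
    min_leaf: int = 2

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.m is not None and self.m < 1:
            raise ValidationError("m must be >= 1")


@dataclass
class ForestModel:
    trees: list[DecisionTree]
    bootstrap_indices: list[np.ndarray]
    oob_indices: list[np.ndarray]
    config: ForestConfig
    n_features_in: int


def fit_forest(table: FeatureTable, cfg: ForestConfig = ForestConfig()) -> ForestModel:
    """Bagged forest: per tree, a size-N bootstrap of the rows and per-split
    random feature subsets of size ``m``."""
    if table.n_rows < 2:
        raise ValidationError("forest needs at least 2 rows")
    m = cfg.m if cfg.m is not None else default_feature_subsample(table.n_features)
    if m > table.n_features:
        raise ValidationError(
            f"m={m} exceeds the {table.n_features} available features"
        )
    all_rows = np.arange(table.n_rows)
    trees, boots, oobs = [], [], []
    for child in np.random.SeedSequence(cfg.seed).spawn(cfg.n_trees):
        rng = np.random.default_rng(child)
        boot = rng.integers(0, table.n_rows, table.n_rows)
        oob = np.setdiff1d(all_rows, boot)
        tree = fit_tree_arrays(
            table.X[boot], table.y[boot], None, cfg.min_leaf, rng, m
        )
        tree.n_features_in = table.n_features
        trees.append(tree)
        boots.append(boot)
        oobs.append(oob)
    return ForestModel(trees, boots, oobs, cfg, table.n_features)


def predict_forest(
    model: ForestModel, X: np.ndarray, y_true: np.ndarray | None = None
) -> ScoredPredictions:
    """Score = fraction of trees voting positive; a 0.5 tie is positive."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    votes = np.stack([t.predict(X) for t in model.trees])
    scores = votes.mean(axis=0)
    return ScoredPredictions(y_true, scores, (scores >= 0.5).astype(np.int8))


def feature_importances(model: ForestModel) -> np.ndarray:
    """Mean decrease in impurity per feature, normalized to sum 1 when nonzero.

    Each internal node contributes its information gain weighted by the
    fraction of the tree's samples reaching it.
    """
    total = np.zeros(model.n_features_in)
    for tree in model.trees:
        internal = tree.feature >= 0
        weights = tree.gain[internal] * tree.n_samples[internal] / tree.n_samples[0]
        np.add.at(total, tree.feature[internal], weights)
    s = total.sum()
    return total / s if s > 0 else total


def nna_predict(
    train: FeatureTable, X: np.ndarray, y_true: np.ndarray | None = None
) -> ScoredPredictions:
    """1-nearest-neighbor prediction; distance ties go to the lowest row index."""
    if train.n_rows == 0:
        raise ValidationError("empty training table")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != train.n_features:
        raise ValidationError(
            f"query has {X.shape[1]} features, training table has {train.n_features}"
        )
    nearest = np.argmin(cdist(X, train.X), axis=1)  # argmin returns the first minimum
    labels = train.y[nearest]
    return ScoredPredictions(y_true, labels.astype(np.float64), labels)


def forest_factory(cfg: ForestConfig = ForestConfig()):
    """Classifier factory for the cross-validation harness."""

    def fit(table: FeatureTable, seed: int) -> Predictor:
        model = fit_forest(table, ForestConfig(cfg.n_trees, cfg.m, seed, cfg.min_leaf))
        return lambda X: predict_forest(model, X)

    return fit


def nna_factory():
    """Nearest-neighbor factory for the cross-validation harness."""

    def fit(table: FeatureTable, seed: int) -> Predictor:
        return lambda X: nna_predict(table, X)

    return fit
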