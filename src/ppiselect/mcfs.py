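"""Monte Carlo feature selection: relative-importance (RI) scores and ranking.

The procedure repeatedly (``T`` rounds) draws a random feature subset and
grows ``M`` decision trees on bootstrap samples restricted to that
subset.  Every tree contributes to the RI score of each feature ``g`` it
splits on:

    RI_g = sum over trees  wAcc^u * sum over nodes splitting on g of
           IG(node) * (n_node / n_tree)^v

where ``wAcc`` is the tree's weighted (balanced) accuracy measured on its
out-of-bag rows, ``IG`` the information gain of the split node, and
``n_node / n_tree`` the fraction of the tree's training samples reaching
the node.  Features are ranked by decreasing RI; ties break toward the
lower original column index.

``wAcc`` is taken as the mean of per-class recalls (balanced accuracy);
when a tree has no out-of-bag rows, its training rows are used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import DecisionTree, fit_tree_arrays
from .dataset_io import FeatureTable
from .errors import ValidationError
from .evaluation import derive_seed


@dataclass(frozen=True)
class MCFSConfig:
    """Monte Carlo feature-selection parameters.

    ``M`` is the number of trees per subset round and ``T`` the number of
    rounds.  The reference implementation of the procedure uses
    M=2000, T=5; the defaults here are desk-scale.  ``subset_size``
    defaults to ``ceil(0.1 * n_features)``.  For a ranking to cover all
    features, ``T * subset_size`` should comfortably exceed the feature
    count — prefer raising ``T`` over ``M`` at small scale.
    """

    u: float = 1.0
    v: float = 1.0
    M: int = 50
    T: int = 5
    subset_size: int | None = None
    bootstrap: bool = True
    min_leaf: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.u < 0 or self.v < 0:
            raise ValidationError("u and v must be >= 0")
        if self.M < 1 or self.T < 1:
            raise ValidationError("M and T must be >= 1")
        if self.subset_size is not None and self.subset_size < 1:
            raise ValidationError("subset_size must be >= 1")


@dataclass
class MCFSResult:
    ri: np.ndarray  # per-feature RI score, >= 0
    ranked: np.ndarray  # feature indices by decreasing RI, ties by ascending index
    config: MCFSConfig
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.ranked) != len(self.ri):
            raise ValidationError("ranked list must cover every feature")

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"f{i}" for i in range(len(self.ri))]
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranked) + 1),
                "feature": [names[i] for i in self.ranked],
                "feature_index": self.ranked,
                "RI": self.ri[self.ranked],
            }
        )


def tree_ri_contribution(tree: DecisionTree, g: int, u: float = 1.0, v: float = 1.0) -> float:
    """One tree's contribution to feature ``g``'s RI score.

    Requires the tree's ``wacc`` attribute (out-of-bag weighted accuracy)
    unless ``u == 0``, in which case the accuracy factor is 1.
    """
    if not 0 <= g < tree.n_features_in:
        raise ValidationError(f"feature index {g} out of range")
    if tree.wacc is None and u != 0:
        raise ValidationError("tree has no recorded weighted accuracy (wacc)")
    at_g = tree.feature == g
    if not at_g.any():
        return 0.0
    frac = tree.n_samples[at_g] / tree.n_samples[0]
    total = float(np.sum(tree.gain[at_g] * frac**v))
    wacc = 1.0 if u == 0 else float(tree.wacc) ** u
    return wacc * total


def _tree_ri_all(tree: DecisionTree, u: float, v: float) -> np.ndarray:
    """Vectorized ``tree_ri_contribution`` over all the tree's features."""
    out = np.zeros(tree.n_features_in)
    internal = tree.feature >= 0
    if not internal.any():
        return out
    frac = tree.n_samples[internal] / tree.n_samples[0]
    np.add.at(out, tree.feature[internal], tree.gain[internal] * frac**v)
    wacc = 1.0 if u == 0 else float(tree.wacc) ** u
    return wacc * out


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    recalls = []
    for c in (0, 1):
        mask = y_true == c
        if mask.any():
            recalls.append(float((y_pred[mask] == c).mean()))
    return float(np.mean(recalls)) if recalls else 0.0


def mcfs_run(table: FeatureTable, cfg: MCFSConfig = MCFSConfig()) -> MCFSResult:
    """Compute RI scores and the ranked feature list for ``table``."""
    if table.n_features < 2:
        raise ValidationError("need at least 2 features")
    if table.n_positive == 0 or table.n_negative == 0:
        raise ValidationError("both classes must be present")
    N = table.n_features
    s = cfg.subset_size if cfg.subset_size is not None else math.ceil(0.1 * N)
    if s > N:
        raise ValidationError(f"subset_size {s} exceeds feature count {N}")

    n = table.n_rows
    ri = np.zeros(N)
    for t in range(cfg.T):
        round_rng = np.random.default_rng(derive_seed(cfg.seed, "round", t))
        subset = np.sort(round_rng.choice(N, size=s, replace=False))
        for j in range(cfg.M):
            tree_rng = np.random.default_rng(derive_seed(cfg.seed, "tree", t, j))
            if cfg.bootstrap:
                boot = tree_rng.integers(0, n, n)
                oob = np.setdiff1d(np.arange(n), boot)
            else:
                boot = np.arange(n)
                oob = np.arange(n)
            tree = fit_tree_arrays(
                table.X[np.ix_(boot, subset)],
                table.y[boot],
                min_leaf=cfg.min_leaf,
                seed=tree_rng,
            )
            eval_rows = oob if len(oob) else boot
            votes = tree.predict(table.X[np.ix_(eval_rows, subset)])
            tree.wacc = _balanced_accuracy(table.y[eval_rows], votes)
            ri[subset] += _tree_ri_all(tree, cfg.u, cfg.v)

    return MCFSResult(ri=ri, ranked=ranked_list(ri), config=cfg, feature_names=list(table.feature_names))


def ranked_list(ri: "np.ndarray | MCFSResult") -> np.ndarray:
    """Feature indices sorted by RI descending, ties by ascending index.

    Accepts either a raw RI vector or an :class:`MCFSResult`.
    """
    if isinstance(ri, MCFSResult):
        return ri.ranked
    ri = np.asarray(ri)
    return np.lexsort((np.arange(len(ri)), -ri)).astype(np.int64)
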