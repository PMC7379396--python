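"""SMOTE oversampling of the minority class.

Each synthetic sample is a convex combination ``z = x + lambda*(y - x)``
of a random minority row ``x`` and a uniformly chosen member ``y`` of its
``k`` nearest minority-class neighbors (Euclidean distance, lambda ~
Uniform(0, 1)).  Samples are appended until the minority/majority ratio
reaches the configured target; original rows are never modified, and
synthetic rows are flagged in their row ids with a ``/smote<i>`` suffix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .dataset_io import FeatureTable
from .errors import NeighborError, ValidationError


@dataclass(frozen=True)
class SmoteConfig:
    k: int = 3
    target_ratio: float = 1.0
    seed: int = 0
    distance: str = "euclidean"
    standardize_before_knn: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ValidationError("target_ratio must be in (0, 1]")
        if self.distance != "euclidean":
            raise ValidationError("only euclidean distance is supported")


def required_synthetic_count(n_min: int, n_maj: int, target_ratio: float = 1.0) -> int:
    """Synthetic samples needed to bring minority/majority up to ``target_ratio``."""
    if n_min >= n_maj:
        raise ValidationError("minority class must be smaller than majority")
    return max(0, math.ceil(target_ratio * n_maj) - n_min)


def smote(table: FeatureTable, cfg: SmoteConfig = SmoteConfig()) -> FeatureTable:
    """Return ``table`` with synthetic minority rows appended.

    Neighbors are searched within the minority class only, excluding the
    sample itself; ties in distance are broken by row order.  Features are
    used on their native scales unless ``standardize_before_knn`` is set.
    """
    minority_label = 1 if table.n_positive < table.n_negative else 0
    min_idx = np.flatnonzero(table.y == minority_label)
    n_min, n_maj = len(min_idx), table.n_rows - len(min_idx)
    if n_min == n_maj:
        warnings.warn("classes already balanced; SMOTE is a no-op", stacklevel=2)
        return table
    n_new = required_synthetic_count(n_min, n_maj, cfg.target_ratio)
    if n_new == 0:
        warnings.warn("minority/majority ratio already at target; SMOTE is a no-op", stacklevel=2)
        return table
    if n_min < cfg.k + 1:
        raise NeighborError(
            f"minority class has {n_min} rows; needs >= k+1 = {cfg.k + 1} for k-NN"
        )

    Xmin = table.X[min_idx]
    Xsearch = Xmin
    if cfg.standardize_before_knn:
        sd = Xmin.std(axis=0)
        sd[sd == 0] = 1.0
        Xsearch = (Xmin - Xmin.mean(axis=0)) / sd
    dist = cdist(Xsearch, Xsearch)
    np.fill_diagonal(dist, np.inf)  # a point is not its own neighbor
    # stable argsort: distance ties are broken by row order
    neighbor_idx = np.argsort(dist, axis=1, kind="stable")[:, : cfg.k]

    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, n_min, n_new)
    pick = rng.integers(0, cfg.k, n_new)
    lam = rng.random(n_new)
    x = Xmin[base]
    ynbr = Xmin[neighbor_idx[base, pick]]
    Z = x + lam[:, None] * (ynbr - x)

    new_ids = [
        f"{table.row_ids[min_idx[b]]}/smote{i}" for i, b in enumerate(base)
    ]
    return FeatureTable(
        table.row_ids + new_ids,
        list(table.feature_names),
        np.vstack([table.X, Z]),
        np.concatenate([table.y, np.full(n_new, minority_label, dtype=np.int8)]),
    )
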