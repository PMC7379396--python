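"""Shadow-feature (Boruta-style) all-relevant feature screening.

Each iteration augments the table with fresh *shadow* features — an
independently row-permuted copy of every original column, which keeps the
marginal distribution but destroys any label association — fits a random
forest on the doubled table, and records impurity importances.  A
feature scores a *hit* in an iteration when its importance exceeds the
maximum importance among all shadow features in that iteration (plus a
configurable margin); it is confirmed important after hits in at least
half of the planned iterations, and rejected as unimportant after that
many failures.  The loop stops when every feature is decided or the
iteration budget is exhausted; the remainder stay undecided.

The per-iteration max-shadow yardstick matters: a pure-noise feature
keeps the same chance association with the label across iterations,
while every shadow draws a fresh one, so a cumulative statistic would
systematically favor lucky noise columns.  Beating the *maximum* of all
fresh shadows in a majority of iterations keeps the false-confirmation
rate on noise features low.  Z-scores (mean importance over its standard
error across iterations) are still computed and reported per feature,
with the max-shadow series as the null yardstick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classifiers import ForestConfig, feature_importances, fit_forest
from .dataset_io import FeatureTable
from .errors import ValidationError
from .evaluation import derive_seed

IMPORTANT = "important"
UNIMPORTANT = "unimportant"
UNDECIDED = "undecided"

SHADOW_PREFIX = "shadow__"

#: iterations of history required before any decision is attempted
MIN_DECISION_ITER = 5


@dataclass(frozen=True)
class BorutaConfig:
    max_iter: int = 100
    n_trees: int = 100
    seed: int = 0
    zscore_margin: float = 0.0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")


@dataclass
class BorutaResult:
    status: list[str]  # per original feature
    importance_history: np.ndarray  # (n_features, n_iterations)
    shadow_history: np.ndarray  # (n_features, n_iterations)
    shadow_max_history: np.ndarray  # (n_iterations,) max shadow importance per iteration
    zscores: np.ndarray
    max_shadow_z: float

    def __post_init__(self) -> None:
        n = len(self.status)
        if self.importance_history.shape[0] != n or self.zscores.shape != (n,):
            raise ValidationError("result dimensions inconsistent")

    @property
    def n_iterations(self) -> int:
        return self.importance_history.shape[1]


def shadow_augment(table: FeatureTable, seed: int = 0) -> FeatureTable:
    """Return a table with each column followed by its shadow copies appended.

    The result has ``2M`` columns: the ``M`` originals, then for each a
    shadow column that is an independent row permutation of it, named with
    the reserved ``shadow__`` prefix.
    """
    if table.n_features < 1:
        raise ValidationError("need at least one feature to shadow")
    rng = np.random.default_rng(seed)
    shadows = np.empty_like(table.X)
    for j in range(table.n_features):
        shadows[:, j] = table.X[rng.permutation(table.n_rows), j]
    return FeatureTable(
        list(table.row_ids),
        list(table.feature_names) + [SHADOW_PREFIX + n for n in table.feature_names],
        np.hstack([table.X, shadows]),
        table.y.copy(),
    )


def _zscores(history: np.ndarray) -> np.ndarray:
    """mean / standard-error per row; 0 where history is identically 0."""
    t = history.shape[1]
    mean = history.mean(axis=1)
    if t < 2:
        return np.where(mean > 0, np.inf, 0.0)
    se = history.std(axis=1, ddof=1) / math.sqrt(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, mean / np.where(se > 0, se, 1.0), np.where(mean > 0, np.inf, 0.0))
    return z


def boruta_run(table: FeatureTable, cfg: BorutaConfig = BorutaConfig()) -> BorutaResult:
    """Run the shadow-feature screening loop on ``table``."""
    if table.n_features < 2:
        raise ValidationError("screening needs at least 2 features")
    if table.n_positive == 0 or table.n_negative == 0:
        raise ValidationError("both classes must be present")

    M = table.n_features
    status = np.array([UNDECIDED] * M, dtype=object)
    hits = np.zeros(M, dtype=np.int64)
    misses = np.zeros(M, dtype=np.int64)
    decide_at = math.ceil(cfg.max_iter / 2)
    orig_hist: list[np.ndarray] = []
    shad_hist: list[np.ndarray] = []

    for it in range(cfg.max_iter):
        it_seed = derive_seed(cfg.seed, "shadow-iter", it)
        augmented = shadow_augment(table, it_seed)
        forest = fit_forest(
            augmented, ForestConfig(n_trees=cfg.n_trees, seed=derive_seed(it_seed, "forest"))
        )
        imp = feature_importances(forest)
        orig_hist.append(imp[:M])
        shad_hist.append(imp[M:])

        undecided = status == UNDECIDED
        beat = orig_hist[-1] > shad_hist[-1].max() + cfg.zscore_margin
        hits[undecided & beat] += 1
        misses[undecided & ~beat] += 1
        if it + 1 >= MIN_DECISION_ITER:
            status[undecided & (hits >= decide_at)] = IMPORTANT
            status[undecided & (misses >= decide_at)] = UNIMPORTANT
            if not (status == UNDECIDED).any():
                break

    oh = np.column_stack(orig_hist)
    sh = np.column_stack(shad_hist)
    shadow_max = sh.max(axis=0)
    return BorutaResult(
        status=list(status),
        importance_history=oh,
        shadow_history=sh,
        shadow_max_history=shadow_max,
        zscores=_zscores(oh),
        max_shadow_z=float(_zscores(shadow_max[None, :])[0]),
    )


def selected_features(result: BorutaResult, keep_undecided: bool = False) -> list[int]:
    """Indices of confirmed (and optionally undecided) features, in column order."""
    keep = {IMPORTANT, UNDECIDED} if keep_undecided else {IMPORTANT}
    return [i for i, s in enumerate(result.status) if s in keep]
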