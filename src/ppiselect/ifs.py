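"""Incremental feature selection, permutation-null bands, and repeated-CV tests.

Given a ranked feature list, IFS cross-validates a classifier on growing
prefixes (top-1, top-2, ...) and records the full metric battery at each
prefix length ``k``.  The *optimal* prefix is the smallest ``k``
attaining the maximum of the chosen metric (F-measure by default); the
*proposed* prefix is the smallest ``k`` whose metric is within a
tolerance ``delta`` of that optimum — trading a sliver of performance
for a much smaller feature set.

Whether the top of the ranking is genuinely informative is assessed
against a permutation null: the retained features are re-ordered at
random many times, an IFS curve is computed for each ordering, and
per-``k`` empirical percentile bands are formed.  The significant prefix
``k*`` is the longest prefix over which the actual curve exceeds the
upper band at every ``k``.

Finally, two feature sets can be compared by repeated cross-validation
with shared fold seeds (true pairing) and a paired t-test on the
per-repeat F-measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import FeatureTable
from .errors import ValidationError
from .evaluation import (
    ClassifierFactory,
    CVConfig,
    MetricsReport,
    cross_validate,
    derive_seed,
)
from .resampling import SmoteConfig


@dataclass
class IFSCurve:
    ks: np.ndarray  # strictly increasing prefix lengths
    reports: list[MetricsReport]
    classifier_tag: str = ""
    ranked_list: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ks = np.asarray(self.ks, dtype=np.int64)
        if len(self.ks) != len(self.reports):
            raise ValidationError("one report per k required")
        if len(self.ks) and np.any(np.diff(self.ks) <= 0):
            raise ValidationError("k grid must be strictly increasing")

    def metric_values(self, metric: str = "f_measure") -> np.ndarray:
        return np.array([r.metric(metric) for r in self.reports])

    def to_frame(self) -> pd.DataFrame:
        rows = [{"k": int(k), **r.to_dict()} for k, r in zip(self.ks, self.reports)]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class IFSSelection:
    optimal_k: int
    optimal_metric: float
    proposed_k: int | None = None
    proposed_metric: float | None = None
    delta: float | None = None
    metric_name: str = "f_measure"

    def __post_init__(self) -> None:
        if self.proposed_k is not None:
            if self.proposed_k > self.optimal_k:
                raise ValidationError("proposed_k must be <= optimal_k")
            if self.delta is not None and self.optimal_metric - self.proposed_metric > self.delta + 1e-12:
                raise ValidationError("proposed metric must be within delta of the optimum")


@dataclass
class PermutationBand:
    ks: np.ndarray
    mean: np.ndarray
    lower: dict[float, np.ndarray]  # level -> per-k lower critical values
    upper: dict[float, np.ndarray]
    n_permutations: int
    null_curves: np.ndarray  # (n_permutations, len(ks))

    def __post_init__(self) -> None:
        for level in self.upper:
            if np.any(self.lower[level] > self.mean + 1e-12) or np.any(
                self.mean > self.upper[level] + 1e-12
            ):
                raise ValidationError("band must satisfy lower <= mean <= upper")

    def to_frame(self) -> pd.DataFrame:
        data = {"k": self.ks, "mean": self.mean}
        for level in sorted(self.lower):
            pct = int(round(level * 100))
            data[f"lo{pct}"] = self.lower[level]
            data[f"hi{pct}"] = self.upper[level]
        return pd.DataFrame(data)


def ifs_run(
    table: FeatureTable,
    ranked: np.ndarray,
    factory: ClassifierFactory,
    cfg: CVConfig,
    k_grid: "np.ndarray | list[int] | None" = None,
    smote_cfg: SmoteConfig | None = None,
    classifier_tag: str = "",
) -> IFSCurve:
    """Cross-validate the classifier on each top-``k`` prefix of ``ranked``."""
    ranked = np.asarray(ranked, dtype=np.int64)
    if ranked.max(initial=-1) >= table.n_features or ranked.min(initial=0) < 0:
        raise ValidationError("ranked list refers to features outside the table")
    ks = np.arange(1, len(ranked) + 1) if k_grid is None else np.asarray(sorted(k_grid))
    if len(ks) == 0 or ks.max() > len(ranked):
        raise ValidationError("k grid exceeds the ranked list length")
    reports = []
    for k in ks:
        sub = table.subset_features(ranked[: int(k)])
        reports.append(cross_validate(sub, factory, cfg, smote_cfg).metrics)
    return IFSCurve(ks, reports, classifier_tag, ranked)


def select_optimal(curve: IFSCurve, metric: str = "f_measure") -> IFSSelection:
    """Smallest k attaining the maximum of ``metric`` along the curve."""
    if not len(curve.ks):
        raise ValidationError("empty curve")
    values = curve.metric_values(metric)
    best = int(np.argmax(values))  # argmax returns the first (smallest-k) maximum
    return IFSSelection(int(curve.ks[best]), float(values[best]), metric_name=metric)


def select_proposed(
    curve: IFSCurve, selection: IFSSelection, delta: float = 0.015
) -> IFSSelection:
    """Smallest k whose metric is within ``delta`` of the optimal metric."""
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    values = curve.metric_values(selection.metric_name)
    ok = np.flatnonzero(values >= selection.optimal_metric - delta)
    j = int(ok[0])
    return replace(
        selection,
        proposed_k=int(curve.ks[j]),
        proposed_metric=float(values[j]),
        delta=delta,
    )


def permutation_bands(
    table: FeatureTable,
    retained: np.ndarray,
    factory: ClassifierFactory,
    cfg: CVConfig,
    n_perm: int = 100,
    levels: tuple[float, ...] = (0.95, 0.99),
    seed: int = 0,
    k_grid: "np.ndarray | list[int] | None" = None,
    smote_cfg: SmoteConfig | None = None,
    metric: str = "f_measure",
) -> tuple[PermutationBand, dict[float, int], IFSCurve]:
    """Permutation-null IFS bands and the significant prefix length per level.

    ``retained`` is the actual ranked list (already restricted to the
    screened features).  ``n_perm`` random re-orderings of it produce
    null IFS curves; per-``k`` empirical percentiles give the critical
    bands (2.5/97.5 for level 0.95, 0.5/99.5 for 0.99).  The verdict for
    a level is the largest prefix length ``k*`` such that the actual
    curve exceeds the upper band at every ``k <= k*``.

    Returns ``(band, verdicts, actual_curve)``.
    """
    retained = np.asarray(retained, dtype=np.int64)
    if len(retained) < 2:
        raise ValidationError("need at least 2 retained features")
    if n_perm < 20 and any(lv >= 0.99 for lv in levels):
        raise ValidationError("n_perm < 20 cannot resolve a 0.99 band")
    ks = np.arange(1, len(retained) + 1) if k_grid is None else np.asarray(sorted(k_grid))

    rng = np.random.default_rng(seed)
    null_curves = np.empty((n_perm, len(ks)))
    for p in range(n_perm):
        order = rng.permutation(retained)
        curve = ifs_run(table, order, factory, cfg, ks, smote_cfg)
        null_curves[p] = curve.metric_values(metric)

    lower, upper = {}, {}
    for level in levels:
        alpha = (1 - level) / 2 * 100
        lower[level] = np.percentile(null_curves, alpha, axis=0)
        upper[level] = np.percentile(null_curves, 100 - alpha, axis=0)
    band = PermutationBand(
        ks, null_curves.mean(axis=0), lower, upper, n_perm, null_curves
    )

    actual = ifs_run(table, retained, factory, cfg, ks, smote_cfg)
    verdicts = {
        level: significant_prefix(actual.metric_values(metric), band.upper[level])
        for level in levels
    }
    return band, verdicts, actual


def significant_prefix(actual: np.ndarray, upper: np.ndarray) -> int:
    """Length of the longest prefix on which ``actual`` strictly exceeds ``upper``."""
    above = np.asarray(actual) > np.asarray(upper)
    if above.all():
        return len(above)
    return int(np.argmin(above))


@dataclass(frozen=True)
class PairedCVReport:
    f_measures_a: np.ndarray
    f_measures_b: np.ndarray
    t_statistic: float
    p_value: float
    degenerate: bool = False

    @property
    def differences(self) -> np.ndarray:
        return self.f_measures_a - self.f_measures_b

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": np.arange(1, len(self.f_measures_a) + 1),
                "arm_a": self.f_measures_a,
                "arm_b": self.f_measures_b,
            }
        )


def repeated_cv_compare(
    table: FeatureTable,
    features_a: np.ndarray,
    features_b: np.ndarray,
    factory: ClassifierFactory,
    cfg: CVConfig,
    smote_cfg: SmoteConfig | None = None,
    metric: str = "f_measure",
) -> PairedCVReport:
    """Paired comparison of two feature sets over repeated cross-validation.

    Both arms use identical fold seeds per repeat (true pairing); the
    per-repeat metric pairs feed a two-sided paired t-test.  With zero
    variance of the differences the t-test is degenerate: the report is
    flagged, with p = 1 for all-zero differences and p ~ 0 otherwise.
    """
    fa, fb = [], []
    for arm, feats, store in (("a", features_a, fa), ("b", features_b, fb)):
        sub = table.subset_features(np.asarray(feats, dtype=np.int64))
        result = cross_validate(sub, factory, cfg, smote_cfg)
        store.extend(r.metric(metric) for r in result.reports)
    a, b = np.array(fa), np.array(fb)
    diff = a - b
    if np.allclose(diff.std(), 0):
        if np.allclose(diff, 0):
            return PairedCVReport(a, b, 0.0, 1.0, degenerate=True)
        return PairedCVReport(a, b, np.inf if diff.mean() > 0 else -np.inf, 0.0, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedCVReport(a, b, float(t), float(p))
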