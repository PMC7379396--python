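"""Confusion-matrix metrics, ROC/PR curves, and the cross-validation harness.

The metric set is the standard binary-classification battery used for
interactome classifiers: sensitivity (SN, = recall), specificity (SP),
overall accuracy (ACC1), balanced accuracy (ACC2 = (SN+SP)/2), Matthews
correlation coefficient (MCC), precision, and F-measure (harmonic mean of
precision and recall).  The interacting (positive) pair class is the
positive class of every metric.  Any ratio with a zero denominator is
defined as 0 so that metric curves remain total on degenerate subsets.

Cross-validation is stratified k-fold with pooled (micro-averaged)
confusion counts; minority oversampling, when enabled, is applied to the
training portion of each fold only — held-out folds are never resampled.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .dataset_io import FeatureTable
from .errors import StratificationError, ValidationError
from .resampling import SmoteConfig, smote


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValidationError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ValidationError("confusion counts must describe at least one sample")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


@dataclass(frozen=True)
class MetricsReport:
    SN: float
    SP: float
    ACC1: float
    ACC2: float
    MCC: float
    precision: float
    f_measure: float
    auroc: float | None = None
    aupr: float | None = None
    counts: ConfusionCounts | None = None

    #: recall is SN by definition
    @property
    def recall(self) -> float:
        return self.SN

    def metric(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            raise ValidationError(f"metric {name!r} unavailable in this report")
        return float(value)

    def to_dict(self) -> dict[str, float]:
        out = {
            "SN": self.SN,
            "SP": self.SP,
            "ACC1": self.ACC1,
            "ACC2": self.ACC2,
            "MCC": self.MCC,
            "recall": self.recall,
            "precision": self.precision,
            "f_measure": self.f_measure,
        }
        if self.auroc is not None:
            out["auroc"] = self.auroc
        if self.aupr is not None:
            out["aupr"] = self.aupr
        return out


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0
    smote_inside_folds: bool = True
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")


@dataclass
class ScoredPredictions:
    """Per-row truth, positive-class score in [0, 1], and hard label."""

    y_true: np.ndarray | None
    scores: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.y_pred = np.asarray(self.y_pred, dtype=np.int8)
        if self.y_true is not None:
            self.y_true = np.asarray(self.y_true, dtype=np.int8)
            if len(self.y_true) != len(self.scores):
                raise ValidationError("y_true and scores lengths differ")
        if len(self.scores) != len(self.y_pred):
            raise ValidationError("scores and y_pred lengths differ")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValidationError("scores must lie in [0, 1]")

    def counts(self) -> ConfusionCounts:
        if self.y_true is None:
            raise ValidationError("true labels unavailable")
        t, p = self.y_true, self.y_pred
        return ConfusionCounts(
            TP=int(((t == 1) & (p == 1)).sum()),
            TN=int(((t == 0) & (p == 0)).sum()),
            FP=int(((t == 0) & (p == 1)).sum()),
            FN=int(((t == 1) & (p == 0)).sum()),
        )


class Predictor(Protocol):
    def __call__(self, X: np.ndarray) -> ScoredPredictions: ...


#: A classifier factory fits on a training table with a seed and returns a predictor.
ClassifierFactory = Callable[[FeatureTable, int], Predictor]


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """All confusion-count metrics, with the zero-denominator-is-0 convention."""
    sn = _safe_div(c.TP, c.TP + c.FN)
    sp = _safe_div(c.TN, c.TN + c.FP)
    prec = _safe_div(c.TP, c.TP + c.FP)
    mcc_den = math.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = _safe_div(c.TP * c.TN - c.FP * c.FN, mcc_den)
    return MetricsReport(
        SN=sn,
        SP=sp,
        ACC1=_safe_div(c.TP + c.TN, c.total),
        ACC2=(sn + sp) / 2,
        MCC=mcc,
        precision=prec,
        f_measure=_safe_div(2 * prec * sn, prec + sn),
        counts=c,
    )


@dataclass(frozen=True)
class CurveResult:
    roc: np.ndarray  # (k, 2) columns fpr, tpr
    pr: np.ndarray  # (k, 2) columns recall, precision
    auroc: float
    aupr: float


def roc_pr_curves(preds: ScoredPredictions) -> CurveResult:
    """ROC and PR curves by threshold sweep over the distinct scores.

    AUROC is the trapezoid area under the ROC curve (equal to the
    Mann-Whitney U statistic over n+ * n-).  AUPR uses the step-wise sum
    with the interpolated precision envelope: at each distinct-score cut
    the precision is replaced by the maximum precision attainable at any
    recall at least as large.  Precision at recall 0 is that of the first
    retrieved point.
    """
    if preds.y_true is None:
        raise ValidationError("curves need true labels")
    y = preds.y_true
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("curves undefined with a single class present")

    order = np.argsort(-preds.scores, kind="stable")
    ys = y[order]
    ss = preds.scores[order]
    # indices of the last element of each tie block of scores
    last = np.flatnonzero(np.r_[ss[1:] != ss[:-1], True])
    tp = np.cumsum(ys == 1)[last].astype(float)
    fp = np.cumsum(ys == 0)[last].astype(float)

    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))

    recall = tp / n_pos
    precision = tp / (tp + fp)
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    steps = np.diff(np.r_[0.0, recall])
    aupr = float(np.sum(steps * envelope))
    pr = np.column_stack([np.r_[0.0, recall], np.r_[envelope[0], precision]])
    return CurveResult(np.column_stack([fpr, tpr]), pr, auroc, aupr)


def make_folds(table: FeatureTable, cfg: CVConfig) -> np.ndarray:
    """Per-row fold assignment in ``0..n_folds-1``; stratified and seeded."""
    if table.n_rows < cfg.n_folds:
        raise ValidationError("fewer rows than folds")
    assignment = np.empty(table.n_rows, dtype=np.int32)
    if cfg.stratified:
        if min(table.n_positive, table.n_negative) < cfg.n_folds:
            raise StratificationError(
                f"smallest class has {min(table.n_positive, table.n_negative)} rows, "
                f"fewer than {cfg.n_folds} folds"
            )
        splitter = StratifiedKFold(cfg.n_folds, shuffle=True, random_state=cfg.seed)
    else:
        splitter = KFold(cfg.n_folds, shuffle=True, random_state=cfg.seed)
    for fold, (_, test_idx) in enumerate(splitter.split(table.X, table.y)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class CVResult:
    """Cross-validation outcome: one report and pooled predictions per repeat."""

    reports: list[MetricsReport]
    predictions: list[ScoredPredictions]

    @property
    def metrics(self) -> MetricsReport:
        """Single report from confusion counts pooled over folds and repeats."""
        if len(self.reports) == 1:
            return self.reports[0]
        total = self.reports[0].counts
        for r in self.reports[1:]:
            total = total + r.counts
        pooled = metrics_from_counts(total)
        aurocs = [r.auroc for r in self.reports if r.auroc is not None]
        auprs = [r.aupr for r in self.reports if r.aupr is not None]
        return replace(
            pooled,
            auroc=float(np.mean(aurocs)) if aurocs else None,
            aupr=float(np.mean(auprs)) if auprs else None,
        )


def derive_seed(seed: int, *tags: object) -> int:
    """Stable sub-seed below 2**31 derived from a master seed and tags."""
    text = ":".join([str(seed), *map(str, tags)])
    return zlib.crc32(text.encode()) % (2**31 - 1)


def cross_validate(
    table: FeatureTable,
    factory: ClassifierFactory,
    cfg: CVConfig,
    smote_cfg: SmoteConfig | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation with per-fold minority oversampling.

    For each fold the classifier is fitted on the remaining folds (after
    SMOTE of the training portion, when ``cfg.smote_inside_folds`` and a
    ``smote_cfg`` are given) and scored on the held-out fold.  Confusion
    counts are pooled over folds; metrics are computed from the pooled
    counts (micro-average).  With ``n_repeats > 1`` the whole procedure is
    repeated with fresh fold seeds.
    """
    reports: list[MetricsReport] = []
    predictions: list[ScoredPredictions] = []
    for rep in range(cfg.n_repeats):
        rep_seed = derive_seed(cfg.seed, "cv-repeat", rep)
        folds = make_folds(table, replace(cfg, seed=rep_seed))
        y_true = np.empty(table.n_rows, dtype=np.int8)
        scores = np.empty(table.n_rows, dtype=np.float64)
        y_pred = np.empty(table.n_rows, dtype=np.int8)
        for fold in range(cfg.n_folds):
            test_mask = folds == fold
            train = table.subset_rows(np.flatnonzero(~test_mask))
            if cfg.smote_inside_folds and smote_cfg is not None:
                fold_seed = derive_seed(rep_seed, "smote", fold)
                train = smote(train, replace(smote_cfg, seed=fold_seed))
            try:
                predictor = factory(train, derive_seed(rep_seed, "fit", fold))
                preds = predictor(table.X[test_mask])
            except Exception as exc:
                raise RuntimeError(f"classifier failed on fold {fold}: {exc}") from exc
            y_true[test_mask] = table.y[test_mask]
            scores[test_mask] = preds.scores
            y_pred[test_mask] = preds.y_pred
        pooled = ScoredPredictions(y_true, scores, y_pred)
        report = metrics_from_counts(pooled.counts())
        if len(np.unique(scores)) > 1 and 0 < pooled.y_true.sum() < len(pooled.y_true):
            curves = roc_pr_curves(pooled)
            report = replace(report, auroc=curves.auroc, aupr=curves.aupr)
        reports.append(report)
        predictions.append(pooled)
    return CVResult(reports, predictions)
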