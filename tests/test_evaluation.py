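import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppiselect import (
    ConfusionCounts,
    CVConfig,
    ScoredPredictions,
    cross_validate,
    make_folds,
    metrics_from_counts,
    roc_pr_curves,
)
from ppiselect.errors import StratificationError, ValidationError

from conftest import make_table


def brute_force_metrics(tp, tn, fp, fn):
    """Independent re-derivation of the metric formulas, scalar by scalar."""
    def div(a, b):
        return a / b if b else 0.0

    sn = div(tp, tp + fn)
    sp = div(tn, tn + fp)
    prec = div(tp, tp + fp)
    den = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) ** 0.5
    return {
        "SN": sn,
        "SP": sp,
        "ACC1": div(tp + tn, tp + tn + fp + fn),
        "ACC2": (sn + sp) / 2,
        "MCC": div(tp * tn - fp * fn, den),
        "recall": sn,
        "precision": prec,
        "f_measure": div(2 * prec * sn, prec + sn),
    }


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics_from_counts(ConfusionCounts(1, 1, 0, 0))
        assert all(v == 1.0 for v in m.to_dict().values())

    def test_degenerate_counts_use_zero_convention(self):
        m = metrics_from_counts(ConfusionCounts(5, 0, 0, 5))
        assert m.MCC == 0.0 and m.SP == 0.0

    def test_hand_worked_example(self):
        m = metrics_from_counts(ConfusionCounts(TP=50, TN=80, FP=20, FN=10))
        expected = {
            "SN": 0.8333, "SP": 0.8000, "ACC1": 0.8125, "ACC2": 0.8167,
            "precision": 0.7143, "f_measure": 0.7692, "MCC": 0.6181,
        }
        for name, value in expected.items():
            assert m.metric(name) == pytest.approx(value, abs=5e-5), name

    def test_oracle_equivalence_on_random_prediction_vectors(self):
        """Metric formulas agree exactly with a per-row confusion tally."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            if not (y == 1).any() and not (p == 1).any() and (y == p).all():
                continue
            tp = int(((y == 1) & (p == 1)).sum())
            tn = int(((y == 0) & (p == 0)).sum())
            fp = int(((y == 0) & (p == 1)).sum())
            fn = int(((y == 1) & (p == 0)).sum())
            report = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
            for name, value in brute_force_metrics(tp, tn, fp, fn).items():
                assert report.metric(name) == pytest.approx(value, abs=1e-12), name

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_ranges(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        m = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
        for name in ("SN", "SP", "ACC1", "ACC2", "precision", "f_measure"):
            assert 0.0 <= m.metric(name) <= 1.0
        assert -1.0 <= m.MCC <= 1.0
        assert m.recall == m.SN


class TestCurves:
    def test_scores_equal_labels(self):
        y = np.array([1, 0, 1, 0, 1])
        preds = ScoredPredictions(y, y.astype(float), y)
        res = roc_pr_curves(preds)
        assert res.auroc == 1.0 and res.aupr == 1.0

    def test_random_scores_give_half_auroc(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 4000)
        s = rng.random(4000)
        res = roc_pr_curves(ScoredPredictions(y, s, (s > 0.5).astype(int)))
        assert res.auroc == pytest.approx(0.5, abs=0.03)

    def test_auroc_equals_mann_whitney(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(5, 25))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            res = roc_pr_curves(ScoredPredictions(y, s, y))
            pos, neg = s[y == 1], s[y == 0]
            u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert res.auroc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-10)

    def test_monotone_transform_leaves_auroc_unchanged(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        a = roc_pr_curves(ScoredPredictions(y, s, y)).auroc
        b = roc_pr_curves(ScoredPredictions(y, s**3, y)).auroc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        y = np.ones(5, dtype=int)
        with pytest.raises(ValidationError):
            roc_pr_curves(ScoredPredictions(y, y.astype(float), y))


class TestFolds:
    def test_partition_and_sizes(self):
        rng = np.random.default_rng(8)
        t = make_table(rng.standard_normal((100, 3)), rng.permutation([1] * 50 + [0] * 50))
        folds = make_folds(t, CVConfig(n_folds=10, seed=1))
        sizes = np.bincount(folds)
        assert sizes.tolist() == [10] * 10

    def test_stratification_exact_when_forced(self):
        rng = np.random.default_rng(9)
        y = np.array([1] * 20 + [0] * 80)
        t = make_table(rng.standard_normal((100, 3)), y)
        folds = make_folds(t, CVConfig(n_folds=10, seed=2))
        for f in range(10):
            assert y[folds == f].sum() == 2

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(10)
        t = make_table(rng.standard_normal((60, 2)), rng.integers(0, 2, 60))
        a = make_folds(t, CVConfig(n_folds=5, seed=3))
        b = make_folds(t, CVConfig(n_folds=5, seed=3))
        assert np.array_equal(a, b)

    def test_too_few_positives_raises(self):
        t = make_table(np.random.default_rng(0).standard_normal((30, 2)), [1] * 3 + [0] * 27)
        with pytest.raises(StratificationError):
            make_folds(t, CVConfig(n_folds=10))


def constant_majority_factory(table, seed):
    label = int(table.y.sum() * 2 > table.n_rows)
    return lambda X: ScoredPredictions(
        None, np.full(len(X), float(label)), np.full(len(X), label, dtype=np.int8)
    )


def stump_factory(table, seed):
    from ppiselect.classifiers import fit_tree

    tree = fit_tree(table, min_leaf=1)
    return lambda X: ScoredPredictions(None, tree.predict(X).astype(float), tree.predict(X))


class TestCrossValidate:
    def test_constant_majority_on_balanced_data(self):
        rng = np.random.default_rng(11)
        t = make_table(rng.standard_normal((100, 3)), [1] * 50 + [0] * 50)
        res = cross_validate(t, constant_majority_factory, CVConfig(n_folds=10, seed=4))
        m = res.metrics
        assert m.ACC1 == pytest.approx(0.5)
        assert m.SN * m.SP == 0.0

    def test_perfect_feature_with_stump(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 80)
        X = np.column_stack([y.astype(float), rng.standard_normal(80)])
        res = cross_validate(make_table(X, y), stump_factory, CVConfig(n_folds=10, seed=5))
        assert res.metrics.f_measure == 1.0

    def test_pooled_counts_cover_the_table(self):
        rng = np.random.default_rng(13)
        t = make_table(rng.standard_normal((90, 3)), rng.permutation([1] * 30 + [0] * 60))
        res = cross_validate(t, constant_majority_factory, CVConfig(n_folds=9, seed=6))
        assert res.metrics.counts.total == 90

    def test_smote_flag_off_reproduces_plain_cv(self, planted):
        from ppiselect import SmoteConfig

        table, _ = planted
        cfg = CVConfig(n_folds=5, seed=7, smote_inside_folds=False)
        with_cfg = cross_validate(table, stump_factory, cfg, SmoteConfig(seed=1))
        without = cross_validate(table, stump_factory, cfg, None)
        assert with_cfg.metrics.counts == without.metrics.counts
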