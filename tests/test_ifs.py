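import numpy as np
import pytest

from ppiselect import (
    CVConfig,
    IFSCurve,
    MetricsReport,
    cross_validate,
    ifs_run,
    permutation_bands,
    repeated_cv_compare,
    select_optimal,
    select_proposed,
)
from ppiselect.classifiers import ForestConfig, forest_factory, nna_factory
from ppiselect.errors import ValidationError
from ppiselect.ifs import significant_prefix

from conftest import make_table


def curve_from_f(ks, fs):
    reports = [
        MetricsReport(SN=f, SP=f, ACC1=f, ACC2=f, MCC=0.0, precision=f, f_measure=f)
        for f in fs
    ]
    return IFSCurve(np.array(ks), reports)


class TestSelection:
    def test_optimal_is_smallest_argmax(self):
        sel = select_optimal(curve_from_f([1, 2, 3], [0.2, 0.5, 0.4]))
        assert sel.optimal_k == 2

    def test_tie_goes_to_smaller_k(self):
        sel = select_optimal(curve_from_f([1, 2], [0.5, 0.5]))
        assert sel.optimal_k == 1

    def test_single_point_curve(self):
        sel = select_optimal(curve_from_f([7], [0.9]))
        assert sel.optimal_k == 7

    def test_proposed_with_zero_delta_equals_optimal(self):
        curve = curve_from_f([1, 2, 3], [0.2, 0.5, 0.4])
        sel = select_proposed(curve, select_optimal(curve), delta=0.0)
        assert sel.proposed_k == sel.optimal_k == 2

    def test_proposed_forced_early(self):
        curve = curve_from_f([3, 100], [0.60, 0.61])
        sel = select_proposed(curve, select_optimal(curve), delta=0.015)
        assert sel.proposed_k == 3

    def test_study_tolerance_admits_the_smaller_model(self):
        # the published pattern: 0.680 at an earlier k is accepted against 0.691
        curve = curve_from_f([90, 166], [0.680, 0.691])
        sel = select_proposed(curve, select_optimal(curve), delta=0.015)
        assert sel.proposed_k == 90

    def test_negative_delta_rejected(self):
        curve = curve_from_f([1], [0.5])
        with pytest.raises(ValidationError):
            select_proposed(curve, select_optimal(curve), delta=-0.1)

    def test_selection_is_pure_function_of_curve(self):
        curve = curve_from_f([1, 2, 3, 4], [0.1, 0.8, 0.8, 0.2])
        a = select_optimal(curve)
        b = select_optimal(curve)
        assert a == b


class TestIFSRun:
    def test_perfect_first_feature(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 60)
        X = np.column_stack([y.astype(float), rng.standard_normal((60, 3))])
        t = make_table(X, y)
        curve = ifs_run(t, np.array([0, 1, 2, 3]), forest_factory(ForestConfig(n_trees=5)),
                        CVConfig(n_folds=5, seed=2), [1])
        assert curve.reports[0].f_measure == 1.0

    def test_full_prefix_equals_plain_cv(self, planted):
        table, _ = planted
        ranked = np.arange(table.n_features)
        cfg = CVConfig(n_folds=5, seed=3)
        factory = nna_factory()
        curve = ifs_run(table, ranked, factory, cfg, [table.n_features])
        plain = cross_validate(table, factory, cfg)
        assert curve.reports[0].f_measure == pytest.approx(plain.metrics.f_measure)

    def test_k_beyond_list_rejected(self, tiny_table):
        with pytest.raises(ValidationError):
            ifs_run(tiny_table, np.array([0, 1]), nna_factory(), CVConfig(n_folds=2), [5])


class TestSignificantPrefix:
    def test_prefix_stops_at_first_failure(self):
        actual = np.array([0.9, 0.9, 0.5, 0.9])
        upper = np.array([0.5, 0.5, 0.5, 0.5])
        assert significant_prefix(actual, upper) == 2

    def test_degenerate_constant_band(self):
        # all permuted curves identical constants: any exceedance at k=1 counts
        assert significant_prefix(np.array([0.8, 0.1]), np.array([0.5, 0.5])) == 1
        assert significant_prefix(np.array([0.5]), np.array([0.5])) == 0

    def test_band_shape_and_levels(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 80)
        X = np.column_stack([y + rng.normal(0, 0.5, 80), rng.standard_normal((80, 5))])
        t = make_table(X, y)
        band, verdicts, actual = permutation_bands(
            t, np.arange(6), nna_factory(), CVConfig(n_folds=4, seed=5),
            n_perm=20, levels=(0.95,), seed=6, k_grid=[1, 2, 3],
        )
        assert band.null_curves.shape == (20, 3)
        assert (band.lower[0.95] <= band.upper[0.95]).all()
        assert 0.95 in verdicts

    def test_small_n_perm_cannot_resolve_99(self, tiny_table):
        with pytest.raises(ValidationError):
            permutation_bands(
                tiny_table, np.array([0, 1]), nna_factory(), CVConfig(n_folds=2),
                n_perm=10, levels=(0.99,),
            )


class TestRepeatedCVCompare:
    @pytest.fixture(scope="class")
    def table(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 80)
        X = np.column_stack([y + rng.normal(0, 0.6, 80), rng.standard_normal((80, 4))])
        return make_table(X, y)

    def test_identical_arms_give_p_one(self, table):
        rep = repeated_cv_compare(
            table, np.array([0, 1]), np.array([0, 1]), nna_factory(),
            CVConfig(n_folds=4, seed=8, n_repeats=10),
        )
        assert rep.p_value == 1.0 and rep.degenerate

    def test_separated_arms_detected(self, table):
        rep = repeated_cv_compare(
            table, np.array([0]), np.array([3, 4]), nna_factory(),
            CVConfig(n_folds=4, seed=9, n_repeats=15),
        )
        assert rep.p_value < 0.01
        assert rep.differences.mean() > 0

    def test_export_frame_has_one_row_per_repeat(self, table):
        rep = repeated_cv_compare(
            table, np.array([0]), np.array([1]), nna_factory(),
            CVConfig(n_folds=4, seed=10, n_repeats=5),
        )
        assert len(rep.to_frame()) == 5
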