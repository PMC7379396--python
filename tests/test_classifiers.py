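import numpy as np
import pytest

from ppiselect import ForestConfig, feature_importances, fit_forest, nna_predict, predict_forest
from ppiselect.classifiers import default_feature_subsample, fit_tree
from ppiselect.errors import ValidationError

from conftest import make_table


class TestTree:
    def test_label_copy_gives_depth_one_tree(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        X = np.column_stack([y.astype(float), rng.standard_normal(50)])
        tree = fit_tree(make_table(X, y), min_leaf=1)
        assert tree.n_internal == 1
        assert (tree.predict(X) == y).all()

    def test_single_class_is_a_leaf(self):
        X = np.random.default_rng(1).standard_normal((10, 3))
        tree = fit_tree(make_table(X, np.ones(10, dtype=int)))
        assert tree.n_nodes == 1 and tree.n_internal == 0

    def test_xor_needs_at_least_three_internal_nodes(self):
        """No depth-1 tree separates XOR (brute force over all single splits),
        but the full tree reaches training accuracy 1.0."""
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (80, 2)).astype(float) + rng.normal(0, 0.01, (80, 2))
        y = (X.round().astype(int)[:, 0] ^ X.round().astype(int)[:, 1]).astype(np.int8)
        # brute force: every single-feature threshold leaves both sides mixed
        for f in range(2):
            for thr in np.unique(X[:, f]):
                left, right = y[X[:, f] <= thr], y[X[:, f] > thr]
                for side in (left, right):
                    if len(side):
                        assert not (
                            len(np.unique(left)) <= 1 and len(np.unique(right)) <= 1
                        )
        tree = fit_tree(make_table(X, y), min_leaf=1)
        assert (tree.predict(X) == y).all()
        assert tree.n_internal >= 3

    def test_consistent_data_fit_exactly_at_min_leaf_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 4))
        y = rng.integers(0, 2, 60)
        tree = fit_tree(make_table(X, y), min_leaf=1)
        assert (tree.predict(X) == y).mean() == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            fit_tree(make_table(np.zeros((0, 2)), np.zeros(0, dtype=int)))


class TestForest:
    @pytest.fixture(scope="class")
    def table(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 120)
        X = np.column_stack([y + rng.normal(0, 0.7, 120), rng.standard_normal((120, 5))])
        return make_table(X, y)

    def test_bootstrap_multisets_have_size_n(self, table):
        model = fit_forest(table, ForestConfig(n_trees=5, seed=1))
        assert all(len(b) == table.n_rows for b in model.bootstrap_indices)

    def test_oob_disjoint_from_bootstrap(self, table):
        model = fit_forest(table, ForestConfig(n_trees=5, seed=2))
        for boot, oob in zip(model.bootstrap_indices, model.oob_indices):
            assert not set(boot) & set(oob)

    def test_scores_are_vote_fractions(self, table):
        model = fit_forest(table, ForestConfig(n_trees=4, seed=3))
        preds = predict_forest(model, table.X)
        assert set(np.round(preds.scores * 4)) <= {0, 1, 2, 3, 4}
        assert ((preds.scores >= 0.5) == (preds.y_pred == 1)).all()

    def test_prediction_invariant_under_tree_order(self, table):
        model = fit_forest(table, ForestConfig(n_trees=7, seed=4))
        before = predict_forest(model, table.X).scores
        model.trees = model.trees[::-1]
        after = predict_forest(model, table.X).scores
        assert np.allclose(before, after)

    def test_m_exceeding_feature_count_rejected(self, table):
        with pytest.raises(ValidationError):
            fit_forest(table, ForestConfig(n_trees=2, m=100))

    def test_ensemble_beats_single_tree_on_planted_data(self, planted):
        """Held-out F-measure of a 50-tree forest >= a single bagged tree, most seeds."""
        from ppiselect import CVConfig, cross_validate
        from ppiselect.classifiers import forest_factory

        table, _ = planted
        wins = 0
        for seed in range(5):
            cfg = CVConfig(n_folds=5, seed=seed)
            big = cross_validate(table, forest_factory(ForestConfig(n_trees=50)), cfg)
            one = cross_validate(table, forest_factory(ForestConfig(n_trees=1)), cfg)
            wins += big.metrics.f_measure >= one.metrics.f_measure
        assert wins >= 4

    def test_importances_concentrate_on_label_copy(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 100)
        X = np.column_stack([rng.standard_normal((100, 3)), y.astype(float)])
        model = fit_forest(make_table(X, y), ForestConfig(n_trees=20, seed=5))
        imp = feature_importances(model)
        assert imp.sum() == pytest.approx(1.0)
        assert imp[3] > 0.8

    def test_default_subspace_size(self):
        assert default_feature_subsample(258) == 9
        assert default_feature_subsample(2) == 2


class TestNNA:
    def test_query_equal_to_training_row(self):
        t = make_table([[0.0, 0.0], [5.0, 5.0]], [0, 1])
        preds = nna_predict(t, np.array([[5.0, 5.0]]))
        assert preds.y_pred[0] == 1

    def test_single_training_row_is_constant(self):
        t = make_table([[1.0, 1.0]], [1])
        preds = nna_predict(t, np.random.default_rng(7).standard_normal((5, 2)))
        assert (preds.y_pred == 1).all()

    def test_midpoint_tie_goes_to_lower_index(self):
        t = make_table([[0.0], [2.0]], [1, 0])
        preds = nna_predict(t, np.array([[1.0]]))
        assert preds.y_pred[0] == 1  # row 0 wins the tie

    def test_dimension_mismatch_rejected(self):
        t = make_table([[0.0, 1.0]], [1])
        with pytest.raises(ValidationError):
            nna_predict(t, np.zeros((1, 3)))
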