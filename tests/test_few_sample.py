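import numpy as np
import pandas as pd
import pytest

from enclasc import (
    FewSampleConfig,
    assign_few_sample,
    build_pair_test_set,
    build_pair_training_set,
    identify_few_sample_classes,
    train_pair_regressor,
)
from enclasc.few_sample import FewSampleScores, aggregate_scores


class TestIdentifyFewSampleClasses:
    def test_boundary_is_inclusive(self):
        # 5 of 1000 == 0.5% exactly: "does not exceed" keeps it
        labels = ["rare"] * 5 + ["big"] * 995
        assert identify_few_sample_classes(labels) == {"rare"}

    def test_just_above_threshold_excluded(self):
        labels = ["rare"] * 6 + ["big"] * 994
        assert identify_few_sample_classes(labels) == set()

    def test_no_rare_classes_gives_empty_set(self):
        labels = ["a"] * 50 + ["b"] * 50
        assert identify_few_sample_classes(labels) == set()


class TestPairConstruction:
    def test_training_pairs_include_self_pairs(self):
        values = np.arange(6, dtype=float).reshape(3, 2)
        X, y = build_pair_training_set(values, ["a", "a", "b"])
        assert X.shape == (9, 4)
        # row j*n + k pairs left cell j with right cell k
        np.testing.assert_array_equal(X[0], [0, 1, 0, 1])
        np.testing.assert_array_equal(X[5], [2, 3, 4, 5])

    def test_same_class_labels_enumerated(self):
        values = np.zeros((3, 1))
        _, y = build_pair_training_set(values, ["a", "a", "b"])
        np.testing.assert_array_equal(y, [1, 1, 0, 1, 1, 0, 0, 0, 1])

    def test_pair_feature_width_is_twice_gene_count(self):
        values = np.zeros((4, 100))
        X, _ = build_pair_training_set(values, ["a", "b", "a", "b"])
        assert X.shape == (16, 200)

    def test_single_cell_cannot_pair(self):
        with pytest.raises(ValueError, match="too few rare cells"):
            build_pair_training_set(np.zeros((1, 3)), ["a"])

    @pytest.mark.parametrize("n,m,d", [(2, 1, 1), (3, 5, 3), (5, 4, 7)])
    def test_test_set_cardinality(self, n, m, d):
        X = build_pair_test_set(np.zeros((n, d)), np.ones((m, d)))
        assert X.shape == (n * m, 2 * d)

    def test_empty_query_gives_empty_test_set(self):
        X = build_pair_test_set(np.zeros((3, 2)), np.zeros((0, 2)))
        assert X.shape == (0, 4)

    def test_reference_left_query_right_ordering(self):
        ref = np.array([[1.0, 1.0], [2.0, 2.0]])
        qry = np.array([[9.0, 9.0]])
        X = build_pair_test_set(ref, qry)
        np.testing.assert_array_equal(X[0], [1, 1, 9, 9])
        np.testing.assert_array_equal(X[1], [2, 2, 9, 9])


class TestPairRegressor:
    def test_separates_two_distant_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.3, size=(8, 4))
        b = rng.normal(6.0, 0.3, size=(4, 4))
        values = np.abs(np.vstack([a, b]))
        labels = ["a"] * 8 + ["b"] * 4
        X, y = build_pair_training_set(values, labels)
        model = train_pair_regressor(X, y, FewSampleConfig(seed=1))
        pred = np.clip(model.predict(X), 0, 1)
        assert pred[y == 1].mean() >= 0.9
        assert pred[y == 0].mean() <= 0.1

    def test_degenerate_labels_error(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="degenerate"):
            train_pair_regressor(X, np.ones(4))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        values = np.abs(rng.normal(1.0, 1.0, size=(10, 5)))
        labels = ["a"] * 6 + ["b"] * 4
        X, y = build_pair_training_set(values, labels)
        p1 = train_pair_regressor(X, y, FewSampleConfig(seed=9)).predict(X)
        p2 = train_pair_regressor(X, y, FewSampleConfig(seed=9)).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestScoreAggregation:
    def test_weighted_mean_formula(self):
        # two reference cells of one class, r = (0.5, 0.25), c = (1, 0):
        # score = (0.5*1 + 0.25*0) / 0.75 = 2/3
        c = np.array([[1.0, 0.0]])
        r = np.array([[0.5, 0.25]])
        scores = aggregate_scores(c, r, ["x", "x"])
        assert scores.loc[0, "x"] == pytest.approx(2.0 / 3.0)

    def test_all_ones_give_score_one(self):
        c = np.ones((3, 4))
        r = np.full((3, 4), 0.5)
        scores = aggregate_scores(c, r, ["x", "x", "y", "y"])
        assert (scores.to_numpy() == 1.0).all()

    def test_nonpositive_weights_fall_back_to_plain_mean(self):
        c = np.array([[0.2, 0.8]])
        r = np.array([[-0.5, 0.0]])
        scores = aggregate_scores(c, r, ["x", "x"])
        assert scores.loc[0, "x"] == pytest.approx(0.5)

    def test_scores_bounded_by_pair_predictions(self):
        rng = np.random.default_rng(4)
        c = rng.random((20, 6))
        r = rng.uniform(-1, 1, size=(20, 6))
        scores = aggregate_scores(c, r, ["x"] * 3 + ["y"] * 3)
        assert (scores.to_numpy() >= 0.0).all()
        assert (scores.to_numpy() <= 1.0).all()


class TestAssignment:
    def _scores(self, rows, classes):
        frame = pd.DataFrame(rows, columns=classes)
        return FewSampleScores(
            scores=frame,
            r=np.zeros((len(rows), 0)),
            c=np.zeros((len(rows), 0)),
            reference_classes=[],
        )

    def test_strictly_above_gamma_assigned(self):
        scores = self._scores([[0.8, 0.1]], ["x", "y"])
        assert assign_few_sample(scores) == ["x"]

    def test_exactly_gamma_rejected(self):
        scores = self._scores([[0.7, 0.1]], ["x", "y"])
        assert assign_few_sample(scores) == ["unassigned"]

    def test_tie_above_gamma_goes_to_smaller_name(self):
        scores = self._scores([[0.9, 0.9]], ["zeta", "alpha"])
        assert assign_few_sample(scores) == ["alpha"]

    def test_no_classes_means_all_unassigned(self):
        scores = self._scores(np.zeros((2, 0)), [])
        assert assign_few_sample(scores) == ["unassigned", "unassigned"]
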