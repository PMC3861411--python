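import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from tfannot.evalstats import (RocCurve, avg_roc_multiclass, nested_cv,
                               stratified_folds, threshold_avg_roc)


class FirstColumnScorer(BaseEstimator, ClassifierMixin):
    """Scores samples by their first feature; fit learns nothing."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def decision_function(self, X):
        return np.asarray(X)[:, 0]

    def predict(self, X):
        return (self.decision_function(X) > 0.5).astype(int)


class ConstantScorer(FirstColumnScorer):
    def decision_function(self, X):
        return np.zeros(len(X))


class TestStratifiedFolds:
    def test_balanced_two_class_assignment(self):
        labels = ["a"] * 4 + ["b"] * 4
        folds = stratified_folds(labels, 4, seed=0)
        for f in range(4):
            chunk = np.asarray(labels)[folds == f]
            assert sorted(chunk) == ["a", "b"]

    def test_determinism_and_proportions(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["x", "y", "z"], size=60, p=[0.5, 0.3, 0.2])
        f1 = stratified_folds(labels, 4, seed=9)
        f2 = stratified_folds(labels, 4, seed=9)
        np.testing.assert_array_equal(f1, f2)
        for f in range(4):
            for c in "xyz":
                in_fold = np.sum((f1 == f) & (labels == c))
                expected = np.sum(labels == c) / 4
                assert abs(in_fold - expected) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            stratified_folds(["a"] * 10 + ["b"] * 2, 4, seed=0)


class TestNestedCv:
    def _data(self, leak=True, n=48, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 3))
        if leak:
            X[:, 0] = y  # the label is readable from the first feature
        return X, y

    def test_oracle_scores_give_avgroc_one(self):
        X, y = self._data(leak=True)
        result = nested_cv(X, y, FirstColumnScorer(), outer=4, seed=1)
        assert result.avg_roc == 1.0
        assert all(c.auc == 1.0 for c in result.curves)

    def test_constant_scores_give_avgroc_half(self):
        X, y = self._data(leak=False)
        result = nested_cv(X, y, ConstantScorer(), outer=4, seed=1)
        assert result.avg_roc == 0.5

    def test_grid_selection_stays_in_inner_loop(self):
        from sklearn.svm import SVC
        X, y = self._data(leak=True, n=64)
        result = nested_cv(X, y, SVC(), {"C": [0.01, 1.0]}, outer=4, seed=2)
        assert len(result.best_params) == 4
        assert result.avg_roc > 0.9


class TestThresholdAvgRoc:
    def _curve(self, scores, labels):
        return RocCurve.from_scores(np.asarray(labels), np.asarray(scores))

    def test_identical_curves_average_to_themselves(self):
        c = self._curve([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        avg = threshold_avg_roc([c, c, c])
        assert avg.auc == pytest.approx(c.auc)
        # operating points reproduce the original curve
        for f, t in zip(c.fpr, c.tpr):
            assert any(np.isclose(avg.fpr, f) & np.isclose(avg.tpr, t))

    def test_two_fold_average_is_pointwise_midpoint(self):
        # same thresholds, symmetric operating points
        c1 = self._curve([0.9, 0.6, 0.4, 0.1], [1, 1, 0, 0])  # perfect
        c2 = self._curve([0.9, 0.6, 0.4, 0.1], [0, 0, 1, 1])  # inverted
        avg = threshold_avg_roc([c1, c2])
        assert avg.auc == pytest.approx(0.5, abs=1e-12)

    def test_output_is_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(4)
        curves = [self._curve(rng.random(20), rng.integers(0, 2, 20))
                  for _ in range(3)]
        avg = threshold_avg_roc(curves)
        assert (np.diff(avg.fpr) >= -1e-12).all()
        assert (np.diff(avg.tpr) >= -1e-12).all()
        assert avg.fpr[0] == 0 and avg.tpr[0] == 0
        assert avg.fpr[-1] == 1 and avg.tpr[-1] == 1


class TestAvgRocMulticlass:
    def test_perfect_separation_gives_one(self):
        labels = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        scores = np.zeros((15, 3))
        for j, c in enumerate(["a", "b", "c"]):
            scores[labels == c, j] = 1.0
        assert avg_roc_multiclass(scores, labels) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(7)
        labels = rng.choice(["a", "b", "c"], size=600)
        scores = rng.normal(size=(600, 3))
        assert avg_roc_multiclass(scores, labels) == pytest.approx(0.5,
                                                                   abs=0.08)

    def test_equals_mean_of_per_class_aucs(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(8)
        labels = rng.choice(["a", "b"], size=40)
        scores = rng.normal(size=(40, 2))
        expected = np.mean([roc_auc_score(labels == "a", scores[:, 0]),
                            roc_auc_score(labels == "b", scores[:, 1])])
        assert avg_roc_multiclass(scores, labels,
                                  classes=["a", "b"]) == pytest.approx(
                                      expected)

    def test_absent_class_skipped_with_warning(self):
        labels = np.array(["a", "a", "b", "b"])
        scores = np.array([[1.0, 0, 0], [0.9, 0, 0],
                           [0.1, 1, 0], [0.0, 1, 0]])
        with pytest.warns(UserWarning, match="absent"):
            value = avg_roc_multiclass(scores, labels,
                                       classes=["a", "b", "c"])
        assert value == 1.0
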