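import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from mslesion.classify import (
    ConfusionCounts,
    compute_metrics,
    confusion_from_predictions,
    five_fold_cv,
    report_tables,
    roc_curve_points,
    serial_fuse,
    train_classifier,
)
from mslesion.errors import DataValidationError, DimensionError


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            # published benchmark rows: AlexNet softmax head and the
            # with-skull random-forest evaluation
            ((93, 5, 94, 8), (93.50, 92.08, 94.90, 92.16, 93.47)),
            ((98, 2, 99, 1), (98.50, 98.99, 98.00, 99.00, 98.49)),
        ],
    )
    def test_reference_rows(self, counts, expected):
        m = compute_metrics(ConfusionCounts(*counts))
        assert (m.AC, m.PR, m.SE, m.SP, m.FS) == expected

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(TP=50, FN=0, TN=50, FP=0))
        assert (m.AC, m.PR, m.SE, m.SP, m.FS) == (100.0, 100.0, 100.0, 100.0, 100.0)

    def test_zero_denominator_reports_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            m = compute_metrics(ConfusionCounts(TP=0, FN=0, TN=10, FP=0))
        assert m.PR == 0.0 and m.SE == 0.0
        assert m.AC == 100.0  # all evaluated samples correct

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_f1_is_harmonic_mean_of_unrounded_pr_se(self, counts):
        tp, fn, tn, fp = counts
        if tp == 0 or (tp + fn + tn + fp) == 0:
            return
        pr = tp / (tp + fp)
        se = tp / (tp + fn)
        harmonic = 100 * 2 * pr * se / (pr + se)
        direct = 100 * 2 * tp / (2 * tp + fn + fp)
        assert direct == pytest.approx(harmonic, abs=1e-9)
        m = compute_metrics(ConfusionCounts(tp, fn, tn, fp))
        assert m.FS == pytest.approx(harmonic, abs=0.005 + 1e-9)

    def test_label_swap_exchanges_se_sp(self):
        m = compute_metrics(ConfusionCounts(TP=40, FN=7, TN=35, FP=3))
        swapped = compute_metrics(ConfusionCounts(TP=35, FN=3, TN=40, FP=7))
        assert m.AC == swapped.AC
        assert (m.SE, m.SP) == (swapped.SP, swapped.SE)

    def test_half_up_rounding_at_exact_tie(self):
        # AC = 100 * 593/800 = 74.125 exactly: half-up gives 74.13
        # (banker's rounding would give 74.12)
        m = compute_metrics(ConfusionCounts(TP=593, FN=0, TN=0, FP=207))
        assert m.AC == 74.13

    def test_empty_evaluation_rejected(self):
        with pytest.raises(DataValidationError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))


class TestSerialFuse:
    def test_deep_block_first(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[5.0], [6.0]])
        fused = serial_fuse(a, b)
        np.testing.assert_array_equal(fused, [[1, 2, 5], [3, 4, 6]])

    def test_realistic_widths(self, rng):
        fused = serial_fuse(rng.random((4, 618)), rng.random((4, 224)))
        assert fused.shape == (4, 842)

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(DimensionError):
            serial_fuse(rng.random((3, 2)), rng.random((4, 2)))

    def test_empty_block_rejected(self, rng):
        with pytest.raises(DimensionError):
            serial_fuse(rng.random((3, 0)), rng.random((3, 2)))


def _separable_toy(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    y = np.array([0, 1] * (n // 2))
    X[y == 1] += 6.0
    return X, y


class TestClassifiers:
    def test_linear_svm_separates_separable_data(self):
        X, y = _separable_toy()
        model = train_classifier(X, y, "SVM-L", seed=0)
        assert (model.predict(X) == y).all()

    def test_knn_majority_vote_hand_oracle(self):
        """1-D points 0..4 (class 0) and 10..14 (class 1): the 5 nearest
        neighbours of any training point are exactly its own cluster."""
        X = np.array([[0], [1], [2], [3], [4], [10], [11], [12], [13], [14]], dtype=float)
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        model = train_classifier(X, y, "KNN", seed=0)
        assert model.predict([[2.0]])[0] == 0
        assert model.predict([[12.0]])[0] == 1
        assert model.predict([[4.0]])[0] == 0  # distances 0..4 beat 6..10

    def test_rf_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        p1 = train_classifier(X, y, "RF", seed=3).predict(X)
        p2 = train_classifier(X, y, "RF", seed=3).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(DataValidationError):
            train_classifier(np.zeros((10, 2)), np.zeros(10), "DT")


class TestFiveFoldCV:
    def test_stratified_folds_of_equal_size(self):
        X, y = _separable_toy(n=200, seed=1)
        result = five_fold_cv(X, y, "DT", seed=0)
        assert len(result.per_fold) == 5
        for fold in result.per_fold:
            assert fold.total == 40
            assert fold.TP + fold.FN == 20  # positives per fold
            assert fold.TN + fold.FP == 20

    def test_pooled_counts_sum_folds_and_cover_dataset(self):
        X, y = _separable_toy(n=100, seed=2)
        result = five_fold_cv(X, y, "NB", seed=1)
        total = sum(f.total for f in result.per_fold)
        assert result.pooled.total == total == 100

    def test_insufficient_samples_rejected(self):
        X = np.zeros((6, 2))
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(DataValidationError):
            five_fold_cv(X, y, "KNN", seed=0)

    def test_separable_data_scores_high(self):
        X, y = _separable_toy(n=100, seed=3)
        for name in ("RF", "KNN", "SVM-L"):
            assert five_fold_cv(X, y, name, seed=0).report.AC >= 95.0


class TestROC:
    def test_perfect_ranking_has_unit_area(self):
        _, area = roc_curve_points([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert area == 1.0

    def test_four_point_hand_example(self):
        """scores (0.1, 0.4, 0.35, 0.8), labels (0, 0, 1, 1): one of the four
        positive-negative pairs is mis-ranked, so AUC = 3/4."""
        points, area = roc_curve_points([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert area == pytest.approx(0.75)
        assert points[0].tolist() == [0.0, 0.0]
        assert points[-1].tolist() == [1.0, 1.0]

    def test_matches_sklearn_on_random_scores(self, rng):
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, size=300)
        labels[:2] = [0, 1]
        _, area = roc_curve_points(scores, labels)
        assert area == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=20_000)
        labels = rng.integers(0, 2, size=20_000)
        _, area = roc_curve_points(scores, labels)
        assert area == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(DataValidationError):
            roc_curve_points([0.1, 0.9], [1, 1])


class TestReportTables:
    def test_layout_and_round_trip(self, tmp_path):
        X, y = _separable_toy(n=60, seed=4)
        results = [five_fold_cv(X, y, name, seed=0) for name in ("RF", "KNN")]
        out = tmp_path / "report.csv"
        table = report_tables(results, out)
        assert list(table.columns) == ["Scheme", "TP", "FN", "TN", "FP", "AC", "PR", "SE", "SP", "FS"]
        assert table["Scheme"].tolist() == ["RF", "KNN"]
        re_read = pd.read_csv(out)
        assert re_read.shape == (2, 10)

    def test_empty_results_rejected(self):
        with pytest.raises(DataValidationError):
            report_tables([])


def test_confusion_from_predictions_counts():
    y_true = np.array([1, 1, 0, 0, 1, 0])
    y_pred = np.array([1, 0, 0, 1, 1, 0])
    c = confusion_from_predictions(y_true, y_pred)
    assert (c.TP, c.FN, c.TN, c.FP) == (2, 1, 2, 1)
    assert c.total == 6
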