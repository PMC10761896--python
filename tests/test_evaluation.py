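"""Metric implementations against brute-force oracles and scikit-learn."""

import numpy as np
import pytest
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix as sk_confusion,
    precision_recall_fscore_support,
)

from phenomlp import (
    CellTable,
    ClassVocabulary,
    aggregate_folds,
    average_precision,
    confusion_matrix,
    evaluate,
    matrix_concordance,
    mean_expression_by_class,
    precision_recall_f1,
)
from phenomlp.core_data import ValidationError


def _random_instance(rng, max_n=50, max_k=6):
    k = int(rng.integers(2, max_k + 1))
    n = int(rng.integers(k, max_n + 1))
    classes = [f"k{i}" for i in range(k)]
    vocab = ClassVocabulary(tuple(classes))
    y_true = [classes[i] for i in rng.integers(0, k, size=n)]
    y_pred = [classes[i] for i in rng.integers(0, k, size=n)]
    return vocab, y_true, y_pred


class TestConfusionMatrix:
    def test_hand_tally(self):
        vocab = ClassVocabulary(("A", "B"))
        cm = confusion_matrix(["A", "A", "B"], ["A", "B", "B"], vocab)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])
        np.testing.assert_allclose(cm.row_percent, [[50, 50], [0, 100]])

    def test_perfect_predictions_are_diagonal(self):
        vocab = ClassVocabulary(("A", "B", "C"))
        y = ["A", "B", "C", "B", "A"]
        cm = confusion_matrix(y, y, vocab)
        assert (np.diag(cm.counts) == [2, 2, 1]).all()
        assert cm.counts.sum() == np.trace(cm.counts)
        np.testing.assert_allclose(np.diag(cm.row_percent), 100.0)

    def test_absent_class_row_is_zero_and_flagged(self):
        vocab = ClassVocabulary(("A", "B", "C"))
        cm = confusion_matrix(["A", "B"], ["A", "B"], vocab)
        assert (cm.counts[2] == 0).all()
        assert cm.empty_rows == ["C"]
        np.testing.assert_allclose(cm.row_percent[2], 0.0)

    def test_length_mismatch_and_unknown_label(self):
        vocab = ClassVocabulary(("A", "B"))
        with pytest.raises(ValidationError):
            confusion_matrix(["A"], ["A", "B"], vocab)
        with pytest.raises(ValidationError):
            confusion_matrix(["A", "Z"], ["A", "B"], vocab)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        vocab, y_true, y_pred = _random_instance(rng)
        cm = confusion_matrix(y_true, y_pred, vocab)
        ref = sk_confusion(y_true, y_pred, labels=list(vocab))
        np.testing.assert_array_equal(cm.counts, ref)
        assert cm.counts.sum() == len(y_true)


class TestPrecisionRecallF1:
    def test_worked_two_class_example(self):
        vocab = ClassVocabulary(("A", "B"))
        m = precision_recall_f1(np.array([[1, 1], [0, 1]]), vocab)
        np.testing.assert_allclose(m.precision, [1.0, 0.5])
        np.testing.assert_allclose(m.recall, [0.5, 1.0])
        np.testing.assert_allclose(m.f1, [2 / 3, 2 / 3], atol=1e-4)
        assert m.macro_f1 == pytest.approx(2 / 3, abs=1e-4)

    def test_diagonal_matrix_is_all_ones(self):
        vocab = ClassVocabulary(("A", "B", "C"))
        m = precision_recall_f1(np.diag([5, 2, 9]), vocab)
        np.testing.assert_allclose([m.macro_precision, m.macro_recall, m.macro_f1], 1.0)

    def test_zero_denominators_reported_as_zero_with_flag(self):
        vocab = ClassVocabulary(("A", "B"))
        # nothing ever predicted or truly B
        m = precision_recall_f1(np.array([[3, 0], [0, 0]]), vocab)
        assert m.precision[1] == 0.0 and m.recall[1] == 0.0
        assert m.undefined["precision"] == ["B"]
        assert m.undefined["recall"] == ["B"]
        assert m.undefined["f1"] == ["B"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_tally_and_sklearn(self, seed):
        rng = np.random.default_rng(100 + seed)
        vocab, y_true, y_pred = _random_instance(rng)
        cm = confusion_matrix(y_true, y_pred, vocab)
        m = precision_recall_f1(cm)
        # brute-force per-class tally from the raw label pairs
        for c, name in enumerate(vocab):
            tp = sum(t == name and p == name for t, p in zip(y_true, y_pred))
            fp = sum(t != name and p == name for t, p in zip(y_true, y_pred))
            fn = sum(t == name and p != name for t, p in zip(y_true, y_pred))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert m.precision[c] == pytest.approx(prec, abs=1e-9)
            assert m.recall[c] == pytest.approx(rec, abs=1e-9)
            assert m.f1[c] == pytest.approx(f1, abs=1e-9)
        sp, sr, sf, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=list(vocab), zero_division=0
        )
        np.testing.assert_allclose(m.precision, sp, atol=1e-9)
        np.testing.assert_allclose(m.recall, sr, atol=1e-9)
        np.testing.assert_allclose(m.f1, sf, atol=1e-9)

    def test_non_square_rejected(self):
        with pytest.raises(ValidationError):
            precision_recall_f1(np.zeros((2, 3)), ClassVocabulary(("A", "B")))


def _ap_bruteforce(truth, scores):
    """Sweep every distinct score as a threshold, accumulating step-wise AP."""
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = truth.sum()
    ap, prev_recall = 0.0, 0.0
    for thr in sorted(set(scores), reverse=True):
        sel = scores >= thr
        tp = np.sum(truth & sel)
        precision = tp / sel.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestAveragePrecision:
    def test_perfect_ranking_is_one(self):
        pr = average_precision([1, 0], [0.9, 0.1])
        assert pr.average_precision == pytest.approx(1.0)

    def test_reversed_two_item_ranking_is_half(self):
        pr = average_precision([1, 0], [0.1, 0.9])
        assert pr.average_precision == pytest.approx(0.5)

    def test_reversed_ranking_with_one_positive_in_n(self):
        n = 10
        truth = [0] * (n - 1) + [1]
        scores = np.linspace(1, 0.1, n)  # positive scored lowest
        pr = average_precision(truth, scores)
        assert pr.average_precision == pytest.approx(1.0 / n)

    def test_recall_is_nondecreasing_along_sweep(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 2, 50)
        truth[0] = 1
        pr = average_precision(truth, rng.normal(size=50))
        assert (np.diff(pr.recall) >= -1e-12).all()

    def test_tied_scores_collapse_into_one_threshold(self):
        # two items share a score: they must enter the sweep together
        pr = average_precision([1, 0, 1], [0.5, 0.5, 0.2])
        # group 1: both 0.5 items -> P=1/2, R=1/2; group 2: all -> P=2/3, R=1
        assert pr.thresholds.tolist() == [0.5, 0.2]
        assert pr.average_precision == pytest.approx(0.5 * 0.5 + 0.5 * (2 / 3))

    def test_no_positives_is_explicit_error(self):
        with pytest.raises(ValidationError, match="no positive"):
            average_precision([0, 0], [0.5, 0.3])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_sweep_and_sklearn(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(10, 201))
        truth = rng.integers(0, 2, size=n)
        if truth.sum() == 0:
            truth[0] = 1
        scores = np.round(rng.normal(size=n), 2)  # rounding forces ties
        ap = average_precision(truth, scores).average_precision
        assert ap == pytest.approx(_ap_bruteforce(truth, scores), abs=1e-9)
        assert ap == pytest.approx(average_precision_score(truth, scores), abs=1e-9)


class TestAggregateFolds:
    def _report(self, y_true, y_pred, vocab):
        return evaluate(y_true, y_pred, None, vocab)

    def test_identical_reports_have_zero_sd(self):
        vocab = ClassVocabulary(("A", "B"))
        r = self._report(["A", "B", "A"], ["A", "B", "B"], vocab)
        agg = aggregate_folds([r, r, r])
        for sd in agg.sd.values():
            np.testing.assert_allclose(sd, 0.0, atol=1e-12)
        assert agg.macro_sd["f1"] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_sd_formula(self):
        # folds with macro F1 0.6 and 0.8 -> mean 0.7, sample SD ~0.1414
        vocab = ClassVocabulary(("A", "B"))
        r1 = self._report(["A", "B"] * 5, ["A", "B"] * 5, vocab)
        r2 = self._report(["A", "B"] * 5, ["B", "A"] * 5, vocab)
        f1s = [r1.metrics.macro_f1, r2.metrics.macro_f1]
        agg = aggregate_folds([r1, r2])
        assert agg.macro_mean["f1"] == pytest.approx(np.mean(f1s))
        expect_sd = abs(f1s[0] - f1s[1]) / np.sqrt(2)
        assert agg.macro_sd["f1"] == pytest.approx(expect_sd, abs=1e-12)

    def test_matches_elementwise_mean_sd_oracle(self):
        rng = np.random.default_rng(5)
        vocab = ClassVocabulary(("A", "B", "C"))
        reports = []
        for _ in range(5):
            _, y_true, y_pred = _coerce(rng, vocab)
            reports.append(self._report(y_true, y_pred, vocab))
        agg = aggregate_folds(reports)
        stack = np.array([r.metrics.f1 for r in reports])
        np.testing.assert_allclose(agg.mean["f1"], stack.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(agg.sd["f1"], stack.std(axis=0, ddof=1), atol=1e-12)

    def test_needs_two_reports_and_matching_vocab(self):
        vocab = ClassVocabulary(("A", "B"))
        r = self._report(["A", "B"], ["A", "B"], vocab)
        with pytest.raises(ValidationError):
            aggregate_folds([r])
        other = self._report(["X", "Y"], ["X", "Y"], ClassVocabulary(("X", "Y")))
        with pytest.raises(ValidationError):
            aggregate_folds([r, other])


def _coerce(rng, vocab):
    classes = list(vocab)
    n = int(rng.integers(6, 30))
    y_true = [classes[i] for i in rng.integers(0, len(classes), n)]
    y_pred = [classes[i] for i in rng.integers(0, len(classes), n)]
    return vocab, y_true, y_pred


class TestMeanExpression:
    def _table(self, expr, labels):
        n = len(labels)
        return CellTable.from_arrays(
            markers=[f"m{i}" for i in range(expr.shape[1])],
            cell_id=[f"c{i}" for i in range(n)], case_id=["x"] * n,
            fov_id=["f"] * n, run_id=["r"] * n, area=[1] * n,
            expression=expr, label=labels,
        )

    def test_single_class_single_marker_mean(self):
        table = self._table(np.array([[2.0], [4.0]]), ["A", "A"])
        m = mean_expression_by_class(table, ["A", "A"], ClassVocabulary(("A", "B")))
        assert m.values[0, 0] == pytest.approx(3.0)
        assert m.empty_classes == ["B"]
        assert np.isnan(m.values[1]).all()

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(6)
        expr = rng.gamma(2, 1, size=(40, 4))
        labels = [f"k{i}" for i in rng.integers(0, 3, 40)]
        vocab = ClassVocabulary(("k0", "k1", "k2"))
        m = mean_expression_by_class(self._table(expr, labels), labels, vocab)
        for c, name in enumerate(vocab):
            rows = [i for i, l in enumerate(labels) if l == name]
            np.testing.assert_allclose(m.values[c], expr[rows].mean(axis=0), atol=1e-12)

    def test_ground_truth_vs_perfect_prediction_identical(self):
        rng = np.random.default_rng(7)
        expr = rng.gamma(2, 1, size=(30, 3))
        labels = [f"k{i}" for i in rng.integers(0, 2, 30)]
        vocab = ClassVocabulary(("k0", "k1"))
        table = self._table(expr, labels)
        gt = mean_expression_by_class(table, labels, vocab, "ground_truth")
        pred = mean_expression_by_class(table, labels, vocab, "prediction")
        np.testing.assert_array_equal(gt.values, pred.values)
        assert matrix_concordance(gt, pred)["overall"] == pytest.approx(1.0)


class TestConcordance:
    def _mat(self, values, grouping="ground_truth"):
        from phenomlp.evaluation import MeanExpressionMatrix

        return MeanExpressionMatrix(
            ["A", "B"], [f"m{i}" for i in range(values.shape[1])], values, grouping
        )

    def test_affine_transform_gives_unit_correlation(self):
        rng = np.random.default_rng(8)
        v = rng.gamma(2, 1, size=(2, 6))
        out = matrix_concordance(self._mat(v), self._mat(3.0 * v + 2.0))
        assert out["A"] == pytest.approx(1.0)
        assert out["B"] == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        a = rng.gamma(2, 1, size=(2, 8))
        b = rng.gamma(2, 1, size=(2, 8))
        out = matrix_concordance(self._mat(a), self._mat(b))
        for i, c in enumerate(["A", "B"]):
            x, y = a[i], b[i]
            r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert out[c] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_row_is_nan(self):
        a = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        b = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        out = matrix_concordance(self._mat(a), self._mat(b))
        assert np.isnan(out["A"]) and out["B"] == pytest.approx(1.0)


class TestEvaluateReport:
    def test_micro_accuracy_equals_exact_match_fraction(self):
        rng = np.random.default_rng(10)
        vocab, y_true, y_pred = _random_instance(rng)
        report = evaluate(y_true, y_pred, None, vocab)
        micro = np.trace(report.confusion.counts) / report.confusion.counts.sum()
        direct = np.mean([t == p for t, p in zip(y_true, y_pred)])
        assert micro == pytest.approx(direct, abs=1e-12)

    def test_json_round_trip_fields(self, tmp_path):
        vocab = ClassVocabulary(("A", "B"))
        rng = np.random.default_rng(11)
        probs = rng.dirichlet([1, 1], size=6)
        y_true = ["A", "B", "A", "B", "A", "B"]
        y_pred = ["A", "B", "B", "B", "A", "A"]
        report = evaluate(y_true, y_pred, probs, vocab)
        path = tmp_path / "report.json"
        report.to_json(path)
        import json

        d = json.loads(path.read_text())
        assert d["classes"] == ["A", "B"]
        assert d["n_cells"] == 6
        assert np.array(d["confusion_counts"]).sum() == 6
        assert set(d["average_precision"]) == {"A", "B"}
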