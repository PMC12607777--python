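"""Metric suite: counting oracle for confusion, arithmetic for one-vs-rest
collapse, Mann–Whitney oracle for AUC, and cross-dataset aggregation."""

import numpy as np
import pytest

import spectratype as st
from spectratype.classifier import PredictionResult
from spectratype.evaluation import metrics_from_confusion


def pair_count_auc(scores, positives):
    """Brute-force Mann–Whitney: concordant + half ties over all pairs."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        labels = ["a", "a", "b", "b", "c", "c", "d", "d"]
        cm = st.confusion(labels, labels, ["a", "b", "c", "d"])
        np.testing.assert_array_equal(cm.counts, np.diag([2, 2, 2, 2]))

    def test_single_predicted_column(self):
        cm = st.confusion(["a", "b", "b"], ["a", "a", "a"], ["a", "b"])
        assert cm.counts[:, 1].sum() == 0
        assert cm.counts[:, 0].sum() == 3

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(41)
        classes = ["w", "x", "y", "z"]
        true = list(rng.choice(classes, size=200))
        pred = list(rng.choice(classes, size=200))
        cm = st.confusion(true, pred, classes)
        for i, ci in enumerate(classes):
            for j, cj in enumerate(classes):
                tally = sum(1 for t, p in zip(true, pred) if t == ci and p == cj)
                assert cm.counts[i, j] == tally

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            st.confusion(["a"], ["q"], ["a", "b"])


class TestOneVsRest:
    def test_binary_fixture_arithmetic(self):
        # TP=8, FN=2, TN=9, FP=1
        cm = st.ConfusionMatrix(["pos", "neg"], np.array([[8, 2], [1, 9]]))
        sens, spec = st.one_vs_rest_metrics(cm, 0)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.9)
        base = metrics_from_confusion(cm)
        assert base["balanced_accuracy"] == pytest.approx(0.85)
        assert base["accuracy"] == pytest.approx(17 / 20)

    def test_perfect_classifier(self):
        cm = st.ConfusionMatrix(["a", "b"], np.array([[5, 0], [0, 5]]))
        assert st.one_vs_rest_metrics(cm, 0) == (1.0, 1.0)

    def test_never_correct_class_has_zero_sensitivity(self):
        cm = st.ConfusionMatrix(["a", "b"], np.array([[0, 4], [0, 6]]))
        sens, _ = st.one_vs_rest_metrics(cm, 0)
        assert sens == 0.0

    def test_absent_class_flagged_undefined(self):
        cm = st.ConfusionMatrix(["a", "b"], np.array([[0, 0], [1, 9]]))
        sens, spec = st.one_vs_rest_metrics(cm, 0)
        assert sens is None and spec is not None

    def test_binary_balanced_accuracy_identity(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            counts = rng.integers(1, 30, size=(2, 2))
            cm = st.ConfusionMatrix(["p", "n"], counts)
            sens, spec = st.one_vs_rest_metrics(cm, 0)
            base = metrics_from_confusion(cm)
            # both classes' one-vs-rest collapse mirror each other in binary
            assert base["balanced_accuracy"] == pytest.approx((sens + spec) / 2)


class TestRocAuc:
    def test_perfect_separation(self):
        assert st.roc_auc([0.9, 0.8, 0.4, 0.3], [True, True, False, False]) == 1.0

    def test_three_of_four_concordant_pairs(self):
        assert st.roc_auc([0.9, 0.5, 0.6, 0.2], [True, True, False, False]) == 0.75

    def test_all_ties_give_half(self):
        assert st.roc_auc([0.5] * 6, [True, True, False, False, False, True]) == 0.5

    def test_degenerate_mask_rejected(self):
        with pytest.raises(ValueError):
            st.roc_auc([0.1, 0.2], [True, True])

    def test_matches_pair_count_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
            positives = rng.random(n) < 0.5
            if positives.all() or not positives.any():
                positives[0] = not positives[0]
            assert st.roc_auc(scores, positives) == pytest.approx(
                pair_count_auc(scores, positives), abs=1e-12
            )


def _prediction(true, probs, class_order):
    probs = np.asarray(probs, dtype=float)
    pred_labels = [class_order[i] for i in np.argmax(probs, axis=1)]
    ids = [f"s{i}" for i in range(len(true))]
    return PredictionResult(ids, probs, pred_labels, class_order), dict(zip(ids, true))


class TestEvaluateDataset:
    def test_perfect_predictions_all_ones(self):
        true = ["a", "b", "a", "b"]
        probs = [[0.9, 0.1], [0.1, 0.9], [0.8, 0.2], [0.2, 0.8]]
        pred, truth = _prediction(true, probs, ["a", "b"])
        report = st.evaluate_dataset(pred, truth)
        assert report.accuracy == 1.0
        assert report.balanced_accuracy == 1.0
        assert report.macro_auc == 1.0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(44)
        true = list(rng.choice(["a", "b", "c"], size=30))
        probs = rng.dirichlet(np.ones(3), size=30)
        pred, truth = _prediction(true, probs, ["a", "b", "c"])
        r1 = st.evaluate_dataset(pred, truth)
        perm = rng.permutation(30)
        shuffled = PredictionResult(
            [pred.sample_ids[i] for i in perm],
            pred.probabilities[perm],
            [pred.predicted_labels[i] for i in perm],
            pred.class_order,
        )
        r2 = st.evaluate_dataset(shuffled, truth)
        assert r1.accuracy == r2.accuracy
        assert r1.balanced_accuracy == pytest.approx(r2.balanced_accuracy)
        np.testing.assert_allclose(r1.auc, r2.auc)

    def test_id_mismatch_rejected(self):
        pred, truth = _prediction(["a", "b"], [[0.9, 0.1], [0.1, 0.9]], ["a", "b"])
        del truth["s1"]
        with pytest.raises(ValueError, match="missing"):
            st.evaluate_dataset(pred, truth)


class TestAggregate:
    def _report(self, acc, sens, spec, bal):
        return st.MetricsReport(
            class_order=["a", "b"],
            accuracy=acc,
            sensitivity=[sens, sens],
            specificity=[spec, spec],
            balanced_accuracy=bal,
            auc=[None, None],
            macro_sensitivity=sens,
            macro_specificity=spec,
            macro_auc=None,
        )

    def test_per_dataset_sensitivity_mean(self):
        # the four per-dataset sensitivities aggregate to their mean, 0.90
        reports = [self._report(0.9, s, 0.95, 0.9) for s in (0.87, 0.93, 0.93, 0.87)]
        agg = st.aggregate(reports)
        assert agg.macro_sensitivity == pytest.approx(0.90)

    def test_balanced_accuracy_mean_and_display_rounding(self):
        reports = [self._report(0.9, 0.9, 0.95, b) for b in (0.91, 0.95, 0.96, 0.91)]
        agg = st.aggregate(reports)
        assert agg.balanced_accuracy == pytest.approx(0.9325)
        assert '"balanced_accuracy": 0.93' in agg.to_json()

    def test_single_report_is_identity(self):
        r = self._report(0.8, 0.7, 0.9, 0.8)
        agg = st.aggregate([r])
        assert agg.accuracy == r.accuracy
        assert agg.macro_sensitivity == r.macro_sensitivity

    def test_identical_reports_aggregate_to_themselves(self):
        r = self._report(0.85, 0.8, 0.9, 0.85)
        agg = st.aggregate([r, r, r])
        assert agg.accuracy == pytest.approx(r.accuracy)
        assert agg.balanced_accuracy == pytest.approx(r.balanced_accuracy)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            st.aggregate([])

    def test_percent_display_flag(self):
        r = self._report(0.85, 0.8, 0.9, 0.85)
        assert '"accuracy": 85.0' in r.to_json(percent=True)
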