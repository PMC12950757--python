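"""Metric oracles: confusion counts, Mann-Whitney AUC, ROC, histograms."""

import numpy as np
import pytest

import medcss as m


def _pairwise_auc(scores, labels):
    """Brute-force oracle over all positive/negative pairs, ties = 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_hand_worked_example(self):
        acc, recall, f1 = m.confusion_metrics([0.6, 0.4, 0.7, 0.2], [1, 1, 0, 0])
        assert (acc, recall, f1) == (0.5, 0.5, 0.5)

    def test_perfect_scores(self):
        acc, recall, f1 = m.confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert acc == recall == f1 == 1.0

    def test_no_positives_present_recall_flagged(self):
        from medcss.evaluation import _confusion

        acc, recall, f1, defined = _confusion([0.1, 0.2], [0, 0], 0.5)
        assert recall == 0.0 and not defined and acc == 1.0

    def test_threshold_extremes(self, rng):
        scores = rng.random(50)
        labels = (rng.random(50) < 0.4).astype(int)
        _, r0, _ = m.confusion_metrics(scores, labels, threshold=0.0)
        _, r1, _ = m.confusion_metrics(scores, labels, threshold=scores.max() + 0.01)
        assert r0 == 1.0 and r1 == 0.0

    def test_tie_at_threshold_predicts_positive(self):
        acc, recall, _ = m.confusion_metrics([0.5], [1], threshold=0.5)
        assert recall == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            m.confusion_metrics([], [])


class TestAuc:
    def test_four_sample_brute_force(self):
        assert m.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75, abs=1e-12)

    def test_perfect_separation(self):
        assert m.auc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_all_ties(self):
        assert m.auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            m.auc([0.1, 0.9], [1, 1])

    def test_matches_pairwise_and_trapezoid(self):
        rng = np.random.default_rng(77)
        scores = np.round(rng.random(200), 2)  # rounding forces ties
        labels = np.array([0, 1] * 100)
        a = m.auc(scores, labels)
        assert a == pytest.approx(_pairwise_auc(scores, labels), abs=1e-9)
        pts = np.array(m.roc_curve_points(scores, labels))
        assert a == pytest.approx(np.trapezoid(pts[:, 1], pts[:, 0]), abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.random(60)
        labels = (rng.random(60) < 0.5).astype(int)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        assert m.auc(1 / (1 + np.exp(-7 * scores)), labels) == pytest.approx(
            m.auc(scores, labels), abs=1e-12
        )


class TestRocCurve:
    def test_endpoints_and_monotone(self):
        rng = np.random.default_rng(3)
        pts = np.array(m.roc_curve_points(rng.random(40), np.tile([0, 1], 20)))
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0)

    def test_perfect_pair_passes_corner(self):
        pts = m.roc_curve_points([0.9, 0.1], [1, 0])
        assert (0.0, 1.0) in pts

    def test_label_reversal_mirrors_auc(self):
        rng = np.random.default_rng(8)
        scores = rng.random(50)
        labels = np.tile([0, 1], 25)
        assert m.auc(scores, 1 - labels) == pytest.approx(1 - m.auc(scores, labels), abs=1e-12)


class TestProbabilityHistogram:
    def test_all_mass_first_bin(self):
        h = m.probability_histogram(np.zeros(5), np.zeros(5, dtype=int))
        assert h["class0"][0] == 5 and h["class0"][1:].sum() == 0

    def test_counts_conserved(self, rng):
        scores = rng.random(37)
        labels = (rng.random(37) < 0.3).astype(int)
        h = m.probability_histogram(scores, labels)
        assert h["class0"].sum() + h["class1"].sum() == 37

    def test_separation_summary(self):
        scores = np.array([0.1] * 4 + [0.9] * 4)
        labels = np.array([0] * 4 + [1] * 4)
        assert m.probability_histogram(scores, labels)["separation"] == pytest.approx(0.8)


class TestEvalPipelinePurity:
    def test_no_augmentation_at_eval_time(self, tiny_model, tiny_splits):
        """Scores come from the raw normalized volumes: a manual forward on
        the untouched test images reproduces evaluate()'s scores exactly."""
        from medcss.evaluation import predict_scores

        ds = tiny_splits["test"]
        before = ds.images.copy()
        scores = predict_scores(tiny_model, ds)
        manual = m.forward_features(tiny_model, ds.images[:, None]).yhat
        np.testing.assert_array_equal(scores, np.atleast_1d(manual))
        np.testing.assert_array_equal(ds.images, before)  # input not mutated


class TestTransferEvaluate:
    def test_consistent_with_evaluate_on_own_split(self, tiny_model, tiny_splits):
        report = m.evaluate(tiny_model, tiny_splits["test"])
        acc = m.transfer_evaluate(tiny_model, tiny_splits["test"])
        assert acc == pytest.approx(report.acc, abs=1e-12)

    def test_constant_model_on_balanced_target(self, tiny_model_cfg):
        model = m.build_model(tiny_model_cfg, seed=0)
        # zero head -> logit 0 -> score 0.5 -> everything predicted positive
        model.params["head.w"] = np.zeros_like(model.params["head.w"])
        model.params["head.b"] = np.zeros_like(model.params["head.b"])
        images = np.random.default_rng(0).random((8, 12, 12, 12))
        target = m.Dataset(images=images, labels=np.tile([0, 1], 4), split="test")
        assert m.transfer_evaluate(model, target) == pytest.approx(0.5)

    def test_class_count_mismatch_rejected(self, tiny_model, tiny_splits):
        bad = m.Dataset(
            images=tiny_splits["test"].images,
            labels=np.arange(len(tiny_splits["test"])) % 3,
            split="test",
        )
        with pytest.raises(ValueError):
            m.transfer_evaluate(tiny_model, bad)


class TestEvaluateReport:
    def test_report_invariants(self, tiny_model, tiny_splits):
        rep = m.evaluate(tiny_model, tiny_splits["test"])
        assert rep.n == len(tiny_splits["test"])
        pts = np.array(rep.roc)
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        total = np.sum(rep.prob_hist["class0"]) + np.sum(rep.prob_hist["class1"])
        assert total == rep.n
        d = rep.to_dict()
        assert set(d) >= {"acc", "recall", "f1", "auc", "roc", "prob_hist", "n"}
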