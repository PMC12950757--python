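"""Classification metrics, ROC analysis, probability histograms, transfer.

Threshold metrics (accuracy, recall, F1) are reported at 0.5 with label 1
as the positive class — the minority class in vessel-like screening tasks.
AUC is computed two ways that must agree: as the Mann-Whitney pairwise
statistic over all positive/negative score pairs (ties count 1/2), and as
the trapezoidal area under the ROC staircase; the rank-based form is the
one returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .backbone import Model, forward_features
from .data import Dataset

__all__ = [
    "MetricsReport",
    "confusion_metrics",
    "auc",
    "roc_curve_points",
    "probability_histogram",
    "evaluate",
    "transfer_evaluate",
]


@dataclass
class MetricsReport:
    """Metrics for one evaluated split."""

    acc: float
    recall: float
    f1: float
    auc: float
    roc: list  # (fpr, tpr) points
    prob_hist: dict  # per-class binned counts + separation summary
    n: int
    recall_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "acc": self.acc, "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "roc": [(float(a), float(b)) for a, b in self.roc],
            "prob_hist": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                          for k, v in self.prob_hist.items()},
            "n": self.n, "recall_defined": self.recall_defined,
        }


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float).reshape(-1)
    labels = np.asarray(labels).reshape(-1).astype(int)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    return scores, labels


def confusion_metrics(scores, labels, threshold: float = 0.5):
    """(accuracy, recall, F1) at a fixed threshold, positive class = 1.

    A score exactly at the threshold predicts positive. When there are no
    true positives and no false negatives recall is undefined; it is
    reported as 0.0 and flagged via the third element of the returned
    ``recall_defined`` triple-companion (see :func:`evaluate`).
    """
    acc, recall, f1, _ = _confusion(scores, labels, threshold)
    return acc, recall, f1


def _confusion(scores, labels, threshold):
    scores, labels = _check_scores_labels(scores, labels)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    acc = (tp + tn) / len(labels)
    recall_defined = (tp + fn) > 0
    recall = tp / (tp + fn) if recall_defined else 0.0
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom > 0 else 0.0
    return acc, recall, f1, recall_defined


def auc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney statistic.

    Probability that a uniformly drawn positive outscores a uniformly
    drawn negative, with ties counting one half. Requires both classes.
    """
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve_points(scores, labels) -> list[tuple[float, float]]:
    """ROC staircase with a threshold at every distinct score.

    Monotone in FPR, from (0, 0) to (1, 1); the trapezoidal area under
    these points equals :func:`auc` exactly.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC undefined: both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))


def probability_histogram(scores, labels, bins: int = 20) -> dict:
    """Per-class histograms of the predicted positive-class probability.

    Equal-width bins on [0, 1]; also reports a separation summary — the
    absolute difference of the class-conditional mean scores — which
    grows as the two predicted distributions pull apart.
    """
    scores, labels = _check_scores_labels(scores, labels)
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist = {}
    for cls in (0, 1):
        cls_scores = scores[labels == cls]
        hist[f"class{cls}"] = np.histogram(cls_scores, bins=edges)[0]
    m0 = scores[labels == 0].mean() if np.any(labels == 0) else np.nan
    m1 = scores[labels == 1].mean() if np.any(labels == 1) else np.nan
    hist["bin_edges"] = edges
    hist["separation"] = float(abs(m1 - m0)) if np.isfinite(m0) and np.isfinite(m1) else float("nan")
    return hist


def predict_scores(model: Model, dataset: Dataset, batch_size: int = 32) -> np.ndarray:
    """Positive-class scores for every sample of a split."""
    scores = []
    for start in range(0, len(dataset), batch_size):
        idx = np.arange(start, min(start + batch_size, len(dataset)))
        fb = forward_features(model, dataset.batch(idx))
        s = fb.yhat if fb.yhat.ndim == 1 else fb.yhat[:, -1]
        scores.append(np.atleast_1d(s))
    return np.concatenate(scores)


def evaluate(model: Model, dataset: Dataset, batch_size: int = 32, bins: int = 20) -> MetricsReport:
    """Full metrics report for one split."""
    scores = predict_scores(model, dataset, batch_size)
    labels = dataset.labels
    acc, recall, f1, recall_defined = _confusion(scores, labels, 0.5)
    both_classes = len(np.unique(labels)) == 2
    return MetricsReport(
        acc=acc,
        recall=recall,
        f1=f1,
        auc=auc(scores, labels) if both_classes else float("nan"),
        roc=roc_curve_points(scores, labels) if both_classes else [],
        prob_hist=probability_histogram(scores, labels, bins),
        n=len(labels),
        recall_defined=recall_defined,
    )


def transfer_evaluate(model: Model, target: Dataset, batch_size: int = 32) -> float:
    """Accuracy of a frozen model on another dataset's split (no fine-tuning).

    The model is applied as-is to the target volumes and scored at the 0.5
    threshold; only accuracy is reported, matching the usual cross-dataset
    transfer protocol.
    """
    n_target = len(np.unique(target.labels))
    if n_target > model.cfg.num_classes:
        raise ValueError(
            f"target has {n_target} classes but model predicts {model.cfg.num_classes}"
        )
    scores = predict_scores(model, target, batch_size)
    acc, _, _, _ = _confusion(scores, target.labels, 0.5)
    return acc
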