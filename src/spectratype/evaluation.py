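"""Metric suite: accuracy, one-vs-rest sensitivity/specificity, balanced
accuracy, ROC/AUC, and cross-dataset aggregation.

All metrics are reported as proportions in [0, 1]; a ``percent`` display
helper multiplies by 100.  Multiclass sensitivity/specificity collapse the
confusion matrix one-vs-rest per class and macro-average; balanced accuracy
is the macro mean of (sensitivity + specificity)/2, which for a binary
confusion reduces exactly to the usual two-term form.  AUC uses the
rank/midrank (Mann–Whitney) formulation, so score ties are handled
deterministically.  Aggregation across datasets is the unweighted arithmetic
mean of each scalar metric (confusion counts are summed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .classifier import PredictionResult


@dataclass
class ConfusionMatrix:
    """C × C counts; rows = true class, columns = predicted class."""

    class_order: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.class_order)
        if self.counts.shape != (c, c):
            raise ValueError(f"counts shape {self.counts.shape} != ({c}, {c})")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def collapse(self, class_index: int) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FN, FP, TN) for one class."""
        tp = int(self.counts[class_index, class_index])
        fn = int(self.counts[class_index].sum() - tp)
        fp = int(self.counts[:, class_index].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fn, fp, tn


def confusion(true_labels, predicted_labels, class_order) -> ConfusionMatrix:
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors must have equal length")
    unknown = (set(true_labels) | set(predicted_labels)) - set(class_order)
    if unknown:
        raise ValueError(f"labels outside class_order: {sorted(unknown)}")
    counts = _sk_confusion(true_labels, predicted_labels, labels=list(class_order))
    return ConfusionMatrix(list(class_order), counts)


def one_vs_rest_metrics(
    cm: ConfusionMatrix, class_index: int
) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) as proportions; None where undefined."""
    tp, fn, fp, tn = cm.collapse(class_index)
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return sens, spec


def roc_auc(scores, positives) -> float:
    """Trapezoidal AUC == Mann–Whitney U/(n_pos·n_neg) with midrank ties."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    if scores.shape != positives.shape:
        raise ValueError("scores and mask must have equal length")
    n_pos = int(positives.sum())
    if n_pos == 0 or n_pos == positives.size:
        raise ValueError("need at least one positive and one negative")
    return float(roc_auc_score(positives.astype(int), scores))


@dataclass
class MetricsReport:
    """Per-dataset (or aggregated) metric bundle.

    Per-class entries are None where undefined (e.g. a class absent from
    the truth); macro means skip those entries.
    """

    class_order: list[str]
    accuracy: float
    sensitivity: list[float | None]
    specificity: list[float | None]
    balanced_accuracy: float
    auc: list[float | None]
    macro_sensitivity: float
    macro_specificity: float
    macro_auc: float | None
    confusion: ConfusionMatrix | None = None
    n_datasets: int = 1
    extras: dict = field(default_factory=dict)

    def to_json(self, percent: bool = False) -> str:
        def scale(v):
            if v is None:
                return None
            return 100.0 * v if percent else v

        payload = {
            "class_order": self.class_order,
            "accuracy": scale(self.accuracy),
            "sensitivity": [scale(v) for v in self.sensitivity],
            "specificity": [scale(v) for v in self.specificity],
            "balanced_accuracy": scale(self.balanced_accuracy),
            "auc": [scale(v) for v in self.auc],
            "macro_sensitivity": scale(self.macro_sensitivity),
            "macro_specificity": scale(self.macro_specificity),
            "macro_auc": scale(self.macro_auc),
            "n_datasets": self.n_datasets,
            "display": {
                "accuracy": None if self.accuracy is None else round(scale(self.accuracy), 2),
                "balanced_accuracy": round(scale(self.balanced_accuracy), 2),
            },
        }
        if self.confusion is not None:
            payload["confusion"] = {
                "class_order": self.confusion.class_order,
                "counts": self.confusion.counts.tolist(),
            }
        return json.dumps(payload, indent=1)


def _mean_defined(values) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def metrics_from_confusion(cm: ConfusionMatrix) -> dict:
    sens, spec = [], []
    for i in range(len(cm.class_order)):
        s, p = one_vs_rest_metrics(cm, i)
        sens.append(s)
        spec.append(p)
    bal = _mean_defined(
        [(s + p) / 2 for s, p in zip(sens, spec) if s is not None and p is not None]
    )
    return {
        "accuracy": float(np.trace(cm.counts)) / cm.total,
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": bal,
        "macro_sensitivity": _mean_defined(sens),
        "macro_specificity": _mean_defined(spec),
    }


def evaluate_dataset(pred: PredictionResult, true_labels) -> MetricsReport:
    """Full metric suite for one validation cohort.

    ``true_labels`` is a sequence aligned to pred.sample_ids or a mapping
    sample_id → label.
    """
    if hasattr(true_labels, "keys"):
        missing = [s for s in pred.sample_ids if s not in true_labels]
        if missing:
            raise ValueError(f"true labels missing for samples: {missing[:5]}")
        truth = [true_labels[s] for s in pred.sample_ids]
    else:
        truth = list(true_labels)
        if len(truth) != len(pred.sample_ids):
            raise ValueError("true labels do not align with predictions")
    class_order = list(pred.class_order)
    cm = confusion(truth, pred.predicted_labels, class_order)
    base = metrics_from_confusion(cm)
    aucs: list[float | None] = []
    truth_arr = np.asarray(truth, dtype=object)
    for i, cls in enumerate(class_order):
        mask = truth_arr == cls
        if mask.all() or not mask.any():
            aucs.append(None)
        else:
            aucs.append(roc_auc(pred.probabilities[:, i], mask))
    return MetricsReport(
        class_order=class_order,
        auc=aucs,
        macro_auc=_mean_defined(aucs),
        confusion=cm,
        **base,
    )


def aggregate(reports: list[MetricsReport]) -> MetricsReport:
    """Unweighted mean of each scalar metric across datasets.

    Display rounding (2 decimals) happens only at serialization; stored
    values keep full precision.  Confusion counts are summed.
    """
    if not reports:
        raise ValueError("need at least one report to aggregate")
    order = reports[0].class_order
    if any(r.class_order != order for r in reports):
        raise ValueError("reports must share one class vocabulary")
    c = len(order)
    agg_conf = None
    if all(r.confusion is not None for r in reports):
        agg_conf = ConfusionMatrix(
            order, np.sum([r.confusion.counts for r in reports], axis=0)
        )
    return MetricsReport(
        class_order=order,
        accuracy=float(np.mean([r.accuracy for r in reports])),
        sensitivity=[_mean_defined([r.sensitivity[i] for r in reports]) for i in range(c)],
        specificity=[_mean_defined([r.specificity[i] for r in reports]) for i in range(c)],
        balanced_accuracy=float(np.mean([r.balanced_accuracy for r in reports])),
        auc=[_mean_defined([r.auc[i] for r in reports]) for i in range(c)],
        macro_sensitivity=float(np.mean([r.macro_sensitivity for r in reports])),
        macro_specificity=float(np.mean([r.macro_specificity for r in reports])),
        macro_auc=_mean_defined([r.macro_auc for r in reports]),
        confusion=agg_conf,
        n_datasets=len(reports),
    )
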