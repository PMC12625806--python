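"""Confusion matrices and the micro/macro F1 metric surface.

Metrics follow the pooled-count definitions: per class i, precision
TP_i/(TP_i+FP_i), recall TP_i/(TP_i+FN_i), F1 their harmonic mean; micro F1
pools TP/FP/FN over all five classes (and therefore equals accuracy for
single-label classification); macro F1 is the unweighted mean of the
defined per-class F1s.  Classes absent from a test set (zero support and
never predicted) yield undefined metrics reported as NaN and excluded from
the macro average.  Everything is kept at full precision internally;
rounding to two decimals happens only at display.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .annotation import CLASS_NAMES

logger = logging.getLogger(__name__)

N_CLASSES = 5


@dataclass(frozen=True)
class ConfusionMatrix5:
    """5x5 count matrix; rows = actual class, columns = estimated class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_CLASSES, N_CLASSES) or (c < 0).any():
            raise ValueError("confusion matrix must be 5x5 with non-negative counts")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __add__(self, other: "ConfusionMatrix5") -> "ConfusionMatrix5":
        return ConfusionMatrix5(self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=CLASS_NAMES, columns=CLASS_NAMES)


@dataclass(frozen=True)
class MetricsReport:
    """Per-class precision/recall/F1 (in %, NaN where undefined) + summaries."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    micro_f1: float
    macro_f1: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precision_pct": self.precision,
                "recall_pct": self.recall,
                "f1_pct": self.f1,
                "support": self.support,
            },
            index=CLASS_NAMES,
        )


def confusion(y_true, y_pred) -> ConfusionMatrix5:
    """Tally a 5x5 confusion matrix from two equal-length label sequences."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise ValueError("labels must lie in the five-class range 0..4")
    return ConfusionMatrix5(
        _sk_confusion(y_true, y_pred, labels=np.arange(N_CLASSES))
    )


def class_metrics(cm: ConfusionMatrix5, class_index: int) -> tuple[float, float, float]:
    """(precision %, recall %, F1 %) for one class; NaN where undefined."""
    c = cm.counts
    tp = c[class_index, class_index]
    fp = c[:, class_index].sum() - tp
    fn = c[class_index, :].sum() - tp
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan if (math.isnan(precision) or math.isnan(recall)) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    if math.isnan(precision) or math.isnan(recall):
        logger.info(
            "metrics undefined for class %s (no predictions and/or no support)",
            CLASS_NAMES[class_index],
        )
    return (100 * precision, 100 * recall, 100 * f1)


def micro_f1(cm: ConfusionMatrix5) -> float:
    """Micro-averaged F1 in % from pooled TP/FP/FN over all classes."""
    if cm.total == 0:
        raise ValueError("micro F1 undefined for an empty confusion matrix")
    tp = np.trace(cm.counts)
    fp = cm.counts.sum(axis=0) - np.diag(cm.counts)
    fn = cm.counts.sum(axis=1) - np.diag(cm.counts)
    mp = tp / (tp + fp.sum())
    mr = tp / (tp + fn.sum())
    return float(100 * 2 * mp * mr / (mp + mr)) if mp + mr > 0 else 0.0


def macro_f1(cm: ConfusionMatrix5) -> float:
    """Unweighted mean (in %) of the defined per-class F1 scores."""
    f1s = [class_metrics(cm, i)[2] for i in range(N_CLASSES)]
    defined = [v for v in f1s if not math.isnan(v)]
    if not defined:
        raise ValueError("macro F1 undefined: no class has a defined F1")
    return float(np.mean(defined))


def metrics_report(cm: ConfusionMatrix5) -> MetricsReport:
    per_class = np.array([class_metrics(cm, i) for i in range(N_CLASSES)])
    return MetricsReport(
        precision=per_class[:, 0],
        recall=per_class[:, 1],
        f1=per_class[:, 2],
        support=cm.support(),
        micro_f1=micro_f1(cm),
        macro_f1=macro_f1(cm),
    )


def aggregate_folds(reports: list[MetricsReport]) -> pd.DataFrame:
    """Mean and sample (n-1) standard deviation of every metric over folds.

    Folds where a metric is undefined propagate NaN into the aggregate so a
    missing class is visible rather than silently averaged away.
    """
    rows = {}
    for name, attr in (("precision", "precision"), ("recall", "recall"), ("f1", "f1")):
        stacked = np.stack([getattr(r, attr) for r in reports])
        for i, cls in enumerate(CLASS_NAMES):
            rows[f"{name}_{cls}"] = stacked[:, i]
    rows["micro_f1"] = np.array([r.micro_f1 for r in reports])
    rows["macro_f1"] = np.array([r.macro_f1 for r in reports])
    table = pd.DataFrame(
        {
            "mean_pct": {k: np.mean(v) for k, v in rows.items()},
            "std_pct": {k: np.std(v, ddof=1) for k, v in rows.items()},
        }
    )
    return table


def round_display(value: float, decimals: int = 2) -> float:
    """Half-up rounding used when printing percentages next to tables."""
    if math.isnan(value):
        return value
    q = 10**decimals
    return math.floor(value * q + 0.5) / q
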