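"""Confusion-matrix construction and multiclass evaluation metrics.

The K-class confusion matrix has entry (r, c) = number of samples whose
true class is r and predicted class is c.  Per-class precision, recall and
F1 come from the one-vs-rest reduction (TP, FP, FN, TN); single-number
summaries use macro averaging — the unweighted mean over classes with a
defined value — because micro precision/recall collapse to plain accuracy
in single-label multiclass problems.  Micro values are reported alongside
for transparency.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix",
           "one_vs_rest_counts", "metric_report"]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) int64
    class_names: tuple[str, ...] | None = None

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path, class_names=None) -> None:
        names = class_names or self.class_names or [str(i) for i in range(self.n_classes)]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["true\\pred"] + list(names))
            for name, row in zip(names, self.counts):
                w.writerow([name] + [int(v) for v in row])


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"label sequences differ in length: {y_true.shape[0]} vs {y_pred.shape[0]}"
        )
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        bad = np.flatnonzero((arr < 0) | (arr >= n_classes))
        if bad.size:
            raise ValueError(
                f"{name}[{bad[0]}] = {arr[bad[0]]} outside [0, {n_classes})"
            )
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def one_vs_rest_counts(cm: ConfusionMatrix, k: int) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) for class k treated as positive."""
    if not 0 <= k < cm.n_classes:
        raise ValueError(f"class index {k} out of range [0, {cm.n_classes})")
    c = cm.counts
    tp = int(c[k, k])
    fp = int(c[:, k].sum()) - tp
    fn = int(c[k, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


@dataclass(frozen=True)
class MetricsReport:
    precision: tuple[float, ...]   # per class; nan where undefined
    recall: tuple[float, ...]
    f1: tuple[float, ...]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    accuracy: float
    n_undefined: int               # classes excluded from the macro means

    def to_dict(self) -> dict:
        clean = lambda seq: [None if math.isnan(v) else round(v, 6) for v in seq]
        return {
            "per_class": {
                "precision": clean(self.precision),
                "recall": clean(self.recall),
                "f1": clean(self.f1),
            },
            "macro": {"precision": round(self.macro_precision, 6),
                      "recall": round(self.macro_recall, 6),
                      "f1": round(self.macro_f1, 6)},
            "micro": {"precision": round(self.micro_precision, 6),
                      "recall": round(self.micro_recall, 6),
                      "f1": round(self.micro_f1, 6)},
            "accuracy": round(self.accuracy, 6),
            "n_undefined_classes": self.n_undefined,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def as_percent(self, value: float) -> str:
        """Display convention: percentages rounded to 2 decimals."""
        return f"{100.0 * value:.2f}%"


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metric_report(cm: ConfusionMatrix) -> MetricsReport:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    prec, rec, f1 = [], [], []
    tps = fps = fns = 0
    for k in range(cm.n_classes):
        tp, fp, fn, _ = one_vs_rest_counts(cm, k)
        tps, fps, fns = tps + tp, fps + fp, fns + fn
        prec.append(_safe_div(tp, tp + fp))
        rec.append(_safe_div(tp, tp + fn))
        f1.append(_safe_div(2 * tp, 2 * tp + fp + fn))

    def macro(vals):
        ok = [v for v in vals if not math.isnan(v)]
        return sum(ok) / len(ok) if ok else float("nan")

    n_undef = sum(1 for trio in zip(prec, rec, f1) if any(math.isnan(v) for v in trio))
    return MetricsReport(
        precision=tuple(prec), recall=tuple(rec), f1=tuple(f1),
        macro_precision=macro(prec), macro_recall=macro(rec), macro_f1=macro(f1),
        micro_precision=_safe_div(tps, tps + fps),
        micro_recall=_safe_div(tps, tps + fns),
        micro_f1=_safe_div(2 * tps, 2 * tps + fps + fns),
        accuracy=float(np.trace(cm.counts)) / cm.total,
        n_undefined=n_undef,
    )
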