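"""Classifier and detector evaluation.

Confusion matrices normalized per true class (so the diagonal is per-class
recall), per-class / mean / overall accuracy, Cohen's d effect sizes,
per-dataset instance summaries, and greedy-IoU detection precision/recall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .yolo_io import CellAnnotation, CellClass, LabeledImageSet

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "EffectSize",
    "confusion_matrix",
    "accuracy_report",
    "cohens_d",
    "dataset_summary",
    "detection_prf",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K confusion counts indexed (true, predicted), with the
    per-true-class (row) normalization."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def normalized(self) -> np.ndarray:
        """Rows divided by their sums; all-zero rows stay all-zero."""
        counts = np.asarray(self.counts, dtype=float)
        row_sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(row_sums > 0, counts / np.where(row_sums == 0, 1, row_sums), 0.0)
        return out

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.normalized if normalized else self.counts
        return pd.DataFrame(data, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class AccuracyReport:
    """Per-class, unweighted-mean and overall (trace/total) accuracy."""

    labels: tuple[str, ...]
    per_class_accuracy: tuple[float, ...]
    mean_accuracy: float
    overall_accuracy: float


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d: pooled-s.d. standardized difference of two group means."""

    d: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    label_order: Sequence[str],
) -> ConfusionMatrix:
    """Tally (true, predicted) pairs into a K x K matrix in ``label_order``."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs {len(predicted_labels)} predicted"
        )
    known = set(label_order)
    for seq, what in ((true_labels, "true"), (predicted_labels, "predicted")):
        unknown = {s for s in seq if s not in known}
        if unknown:
            raise ValueError(f"unknown {what} labels: {sorted(unknown)}")
    if len(true_labels) == 0:
        counts = np.zeros((len(label_order), len(label_order)), dtype=int)
    else:
        counts = _sk_confusion(true_labels, predicted_labels, labels=list(label_order))
    return ConfusionMatrix(labels=tuple(label_order), counts=counts)


def accuracy_report(matrix: ConfusionMatrix) -> AccuracyReport:
    """Accuracies from a confusion matrix.

    Per-class accuracy is the diagonal of the row-normalized matrix (recall
    per true class); the headline mean is the UNWEIGHTED average of the
    per-class values; overall accuracy is trace/total and therefore weights
    classes by their evaluated counts.
    """
    if len(matrix.labels) < 1:
        raise ValueError("empty confusion matrix")
    per_class = tuple(float(v) for v in np.diag(matrix.normalized))
    total = matrix.total
    overall = float(np.trace(matrix.counts) / total) if total else 0.0
    return AccuracyReport(
        labels=matrix.labels,
        per_class_accuracy=per_class,
        mean_accuracy=float(np.mean(per_class)),
        overall_accuracy=overall,
    )


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> EffectSize:
    """Cohen's d with the pooled standard deviation.

    d = (mean_a - mean_b) / s_p,
    s_p = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)).

    Two groups with equal means (including equal-constant groups with zero
    pooled variance) give d = 0 by convention; swapping the groups negates
    d.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    pooled_var = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n_a + n_b - 2)
    if pooled_var == 0.0:
        if mean_a == mean_b:
            d = 0.0
        else:
            raise ValueError("zero pooled variance with unequal means: d undefined")
    else:
        d = (mean_a - mean_b) / math.sqrt(pooled_var)
    return EffectSize(d=float(d), mean_a=mean_a, mean_b=mean_b, n_a=n_a, n_b=n_b)


def dataset_summary(sets: Mapping[str, LabeledImageSet]) -> pd.DataFrame:
    """Per-class instance counts for each named set, with a Total column.

    Rows are the three cell classes plus an ``All`` row; columns are the
    set names in input order plus ``Total``.
    """
    class_names = [c.display_name for c in CellClass]
    data = {}
    for name, image_set in sets.items():
        tally = {c: 0 for c in CellClass}
        for ann in image_set.annotations():
            tally[ann.cell_class] += 1
        data[name] = [tally[c] for c in CellClass]
    frame = pd.DataFrame(data, index=class_names, dtype=int)
    if frame.empty:
        frame = pd.DataFrame(index=class_names)
    frame["Total"] = frame.sum(axis=1).astype(int) if len(frame.columns) else 0
    frame.loc["All"] = frame.sum(axis=0).astype(int)
    return frame


def _greedy_match(
    truth: Sequence[CellAnnotation],
    pred: Sequence[CellAnnotation],
    iou_min: float,
) -> list[tuple[int, int]]:
    """One-to-one (pred, truth) index pairs: predictions in descending
    confidence order greedily claim the best unmatched same-class truth
    with IoU >= iou_min."""
    order = sorted(
        range(len(pred)),
        key=lambda i: (-(pred[i].confidence if pred[i].confidence is not None else 1.0), i),
    )
    matched_truth: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for pi in order:
        p = pred[pi]
        best_iou, best_ti = iou_min, None
        for ti, t in enumerate(truth):
            if ti in matched_truth or t.cell_class is not p.cell_class:
                continue
            iou = p.box.iou(t.box)
            if iou >= best_iou:
                best_iou, best_ti = iou, ti
        if best_ti is not None:
            matched_truth.add(best_ti)
            pairs.append((pi, best_ti))
    return pairs


def detection_prf(
    truth: Sequence[CellAnnotation],
    pred: Sequence[CellAnnotation],
    iou_min: float = 0.5,
) -> pd.DataFrame:
    """Class-aware detection precision/recall/F1 at an IoU threshold.

    Matching is greedy one-to-one by descending prediction confidence.
    Rows: one per cell class plus a ``micro`` row pooling TP/FP/FN across
    classes.  An undefined precision or recall (zero denominator) is
    reported as 0.0 with the ``undefined`` flag set.
    """
    if not (0.0 < iou_min <= 1.0):
        raise ValueError("iou_min must lie in (0, 1]")
    pairs = _greedy_match(truth, pred, iou_min)
    matched_pred = {pi for pi, _ in pairs}
    rows = []
    totals = {"tp": 0, "fp": 0, "fn": 0}
    for cls in CellClass:
        tp = sum(1 for pi, _ in pairs if pred[pi].cell_class is cls)
        n_pred = sum(1 for p in pred if p.cell_class is cls)
        n_true = sum(1 for t in truth if t.cell_class is cls)
        fp, fn = n_pred - tp, n_true - tp
        rows.append(_prf_row(cls.display_name, tp, fp, fn))
        for key, v in (("tp", tp), ("fp", fp), ("fn", fn)):
            totals[key] += v
    rows.append(_prf_row("micro", totals["tp"], totals["fp"], totals["fn"]))
    return pd.DataFrame(rows).set_index("class")


def _prf_row(name: str, tp: int, fp: int, fn: int) -> dict:
    undefined = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "class": name,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "undefined": undefined,
    }
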