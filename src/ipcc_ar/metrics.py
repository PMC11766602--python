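"""Pixel-overlap accuracy metrics for segmentation and registration.

All metrics derive from the per-pixel confusion table of a predicted binary
mask against a reference mask (foreground = positive class): Dice/F1,
accuracy, precision, recall, Jaccard/IoU, specificity and Cohen's kappa.
Degenerate 0/0 ratios are defined as 0 so that batch evaluation over many
frames never produces NaNs; such tables are simply uninformative frames.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ParameterError
from .ipcc import warp
from .preprocessing import skeletonize
from .transform import SimilarityTransform

__all__ = [
    "ConfusionTable",
    "MetricsRecord",
    "confusion_counts",
    "metrics_from_confusion",
    "evaluate_masks",
    "registration_dice",
    "write_metrics_csv",
]

#: Column order used for CSV output.
METRIC_COLUMNS = (
    "dice",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "jaccard",
    "specificity",
    "iou",
    "cohen_kappa",
)


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsRecord:
    dice: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    jaccard: float
    specificity: float
    iou: float
    cohen_kappa: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionTable:
    """Tabulate per-pixel TP/FP/FN/TN with foreground as the positive class."""
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ParameterError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return ConfusionTable(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def _ratio(num: float, den: float) -> float:
    """num/den with the 0/0 (and x/0) convention of returning 0."""
    return num / den if den > 0 else 0.0


def metrics_from_confusion(c: ConfusionTable) -> MetricsRecord:
    """All overlap metrics from a confusion table.

    dice = 2TP/(2TP+FP+FN) (= F1 on pixels), jaccard = iou = TP/(TP+FP+FN),
    and kappa = (p_o - p_e)/(1 - p_e) with the standard marginal chance
    agreement p_e.
    """
    if c.total <= 0:
        raise ParameterError("empty confusion table")
    tp, fp, fn, tn = float(c.tp), float(c.fp), float(c.fn), float(c.tn)
    n = float(c.total)
    dice = _ratio(2 * tp, 2 * tp + fp + fn)
    jaccard = _ratio(tp, tp + fp + fn)
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = _ratio(p_o - p_e, 1.0 - p_e)
    return MetricsRecord(
        dice=dice,
        accuracy=(tp + tn) / n,
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
        f1=dice,
        jaccard=jaccard,
        specificity=_ratio(tn, tn + fp),
        iou=jaccard,
        cohen_kappa=kappa,
    )


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> MetricsRecord:
    """Convenience: metrics straight from two same-size binary masks."""
    return metrics_from_confusion(confusion_counts(pred, truth))


def registration_dice(
    A: np.ndarray,
    B: np.ndarray,
    T: SimilarityTransform,
    skeleton: bool = True,
) -> float:
    """Dice between ``A`` warped by ``T`` and ``B`` over ``B``'s extent.

    By default both maps are (re-)skeletonized before comparison, matching
    how registration accuracy is scored on vessel centerlines; pass
    ``skeleton=False`` to compare the raw masks.
    """
    h, w = np.asarray(B).shape
    warped = warp(np.asarray(A, dtype=np.uint8), T, out_size=(w, h))
    if skeleton:
        warped = skeletonize(warped)
        B = skeletonize(np.asarray(B, dtype=np.uint8))
    return metrics_from_confusion(confusion_counts(warped, B)).dice


def write_metrics_csv(
    path: str | Path,
    rows: Iterable[tuple[str, MetricsRecord]],
) -> None:
    """Write one metrics row per frame, in the standard column order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("frame",) + METRIC_COLUMNS)
        for name, rec in rows:
            d = rec.as_dict()
            writer.writerow([name] + [f"{d[c]:.6f}" for c in METRIC_COLUMNS])
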