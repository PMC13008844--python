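"""Segmentation evaluation: per-class confusion accumulation and the
mIoU / Recall / Precision / F1 report.

Per-class IoU = TP / (TP + FP + FN); mIoU averages the background and stem
classes.  Recall, Precision and F1 are reported for the stem (positive)
class, the convention for a binary organ-segmentation task.  Percentages are
rounded to two decimals when formatted.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ConfusionMatrix", "MetricReport", "confusion", "metric_report"]

_CLASSES = ("background", "stem")


@dataclass
class ConfusionMatrix:
    """Per-class TP/FP/FN/TN pixel counts for {background, stem}."""

    tp: dict[str, int] = field(default_factory=lambda: {c: 0 for c in _CLASSES})
    fp: dict[str, int] = field(default_factory=lambda: {c: 0 for c in _CLASSES})
    fn: dict[str, int] = field(default_factory=lambda: {c: 0 for c in _CLASSES})
    tn: dict[str, int] = field(default_factory=lambda: {c: 0 for c in _CLASSES})

    @property
    def total(self) -> int:
        c = _CLASSES[0]
        return self.tp[c] + self.fp[c] + self.fn[c] + self.tn[c]

    def update(self, pred: np.ndarray, gt: np.ndarray) -> "ConfusionMatrix":
        """Accumulate counts from one prediction/ground-truth mask pair."""
        pred = np.asarray(pred)
        gt = np.asarray(gt)
        if pred.shape != gt.shape:
            raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
        if not (np.isin(pred, (0, 1)).all() and np.isin(gt, (0, 1)).all()):
            raise ValueError("confusion() requires binary {0,1} masks")
        for cls, val in zip(_CLASSES, (0, 1)):
            p = pred == val
            g = gt == val
            self.tp[cls] += int(np.count_nonzero(p & g))
            self.fp[cls] += int(np.count_nonzero(p & ~g))
            self.fn[cls] += int(np.count_nonzero(~p & g))
            self.tn[cls] += int(np.count_nonzero(~p & ~g))
        return self

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        out = ConfusionMatrix()
        for c in _CLASSES:
            out.tp[c] = self.tp[c] + other.tp[c]
            out.fp[c] = self.fp[c] + other.fp[c]
            out.fn[c] = self.fn[c] + other.fn[c]
            out.tn[c] = self.tn[c] + other.tn[c]
        return out


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionMatrix:
    """Exact integer confusion counts for a binary prediction/label pair."""
    return ConfusionMatrix().update(pred, gt)


@dataclass(frozen=True)
class MetricReport:
    miou: float
    recall: float
    precision: float
    f1: float
    iou_per_class: dict[str, float]

    def as_dict(self) -> dict[str, float]:
        return {
            "mIoU": round(self.miou, 2),
            "Recall": round(self.recall, 2),
            "Precision": round(self.precision, 2),
            "F1": round(self.f1, 2),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    def write_csv(self, path: str | Path) -> None:
        d = self.as_dict()
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(d.keys())
            writer.writerow(f"{v:.2f}" for v in d.values())

    def __str__(self) -> str:
        d = self.as_dict()
        return "  ".join(f"{k} {v:.2f}%" for k, v in d.items())


def metric_report(cm: ConfusionMatrix) -> MetricReport:
    """mIoU over both classes plus stem-class Recall/Precision/F1, in %.

    A class whose union (TP+FP+FN) is empty never occurs and is excluded
    from the mean IoU.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    ious: dict[str, float] = {}
    for c in _CLASSES:
        union = cm.tp[c] + cm.fp[c] + cm.fn[c]
        if union > 0:
            ious[c] = cm.tp[c] / union
    if not ious:
        raise ValueError("no class has a nonempty union")
    miou = 100.0 * float(np.mean(list(ious.values())))

    tp, fp, fn = cm.tp["stem"], cm.fp["stem"], cm.fn["stem"]
    recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return MetricReport(miou, recall, precision, f1, {c: 100.0 * v for c, v in ious.items()})
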