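"""Segmentation evaluation metrics: Dice, IoU, sensitivity, specificity.

All four are exact rational functions of the pixel confusion counts:

    Dice        = 2 TP / (2 TP + FP + FN)
    IoU         = TP / (TP + FP + FN)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)

Degenerate denominators follow the standard benchmark convention: an image
where both ground truth and prediction are empty scores Dice = IoU =
sensitivity = 1 (and likewise specificity 1 when there is no background);
an empty ground truth with a non-empty prediction scores 0 through TP = 0.

Set-level mDice/mIoU aggregate per image (unweighted arithmetic mean of the
per-image values), not by pooling pixels across images.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "dice",
    "iou",
    "sensitivity",
    "specificity",
    "evaluate_set",
    "write_report",
]


@dataclass
class ConfusionCounts:
    """Pixel confusion counts for one predicted/reference mask pair."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Per-image metrics and their unweighted means over a test set."""

    per_image: List[Tuple[float, float, float, float]]  # (dice, iou, sens, spec)
    mean_dice: float
    mean_iou: float
    mean_sensitivity: float
    mean_specificity: float
    image_ids: List[str]


def _as_binary(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D mask, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return arr.astype(bool)


def confusion(pred, gt) -> ConfusionCounts:
    """Exact pixel confusion counts of two equal-size binary masks."""
    p = _as_binary(pred, "pred")
    g = _as_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.sum(p & g))
    tn = int(np.sum(~p & ~g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def dice(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2.0 * c.tp / denom


def iou(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    return 1.0 if denom == 0 else c.tp / denom


def specificity(c: ConfusionCounts) -> float:
    denom = c.tn + c.fp
    return 1.0 if denom == 0 else c.tn / denom


def evaluate_set(preds: Sequence, gts: Sequence, image_ids=None) -> MetricsReport:
    """Per-image Dice/IoU/sensitivity/specificity plus their means."""
    if len(preds) != len(gts):
        raise ValueError(f"got {len(preds)} predictions for {len(gts)} references")
    if len(preds) == 0:
        raise ValueError("cannot evaluate an empty set")
    if image_ids is None:
        image_ids = [f"image_{i:04d}" for i in range(len(preds))]
    per_image = []
    for p, g in zip(preds, gts):
        c = confusion(p, g)
        per_image.append((dice(c), iou(c), sensitivity(c), specificity(c)))
    arr = np.asarray(per_image)
    means = arr.mean(axis=0)
    return MetricsReport(
        per_image=per_image,
        mean_dice=float(means[0]),
        mean_iou=float(means[1]),
        mean_sensitivity=float(means[2]),
        mean_specificity=float(means[3]),
        image_ids=list(image_ids),
    )


def write_report(report: MetricsReport, csv_path, json_path) -> None:
    """Write per-image metrics as CSV and the summary means as JSON."""
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "dice", "iou", "sensitivity", "specificity"])
        for img_id, row in zip(report.image_ids, report.per_image):
            writer.writerow([img_id] + [f"{v:.6f}" for v in row])
    summary = {
        "n_images": len(report.per_image),
        "mean_dice": report.mean_dice,
        "mean_iou": report.mean_iou,
        "mean_sensitivity": report.mean_sensitivity,
        "mean_specificity": report.mean_specificity,
    }
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
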