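"""Binary segmentation metrics: F1 (Dice), IoU (Jaccard), pixel accuracy.

All three are computed from one confusion-count pass over a predicted and a
ground-truth binary mask.  F1 and IoU are foreground-sensitive (they ignore
true negatives); accuracy is label-symmetric.  The two satisfy the identity
``IoU = F1 / (2 - F1)`` for any confusion counts.

When both masks are entirely empty, F1 and IoU are defined as 1.0 by
convention (a perfect prediction of "nothing"); this case is degenerate in
the ratio formulas and the convention is pinned by tests.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "f1",
    "iou",
    "accuracy",
    "evaluate_masks",
    "write_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def _require_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} mask must be strictly binary (0/1)")
    return arr.astype(bool)


def confusion(pred_binary, truth_binary) -> ConfusionCounts:
    """Pixel confusion counts between two binary masks of identical shape."""
    pred = _require_binary(pred_binary, "predicted")
    truth = _require_binary(truth_binary, "truth")
    if pred.shape != truth.shape:
        raise ValueError(
            f"mask shapes differ: predicted {pred.shape} vs truth {truth.shape}"
        )
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall (equals the Dice coefficient)."""
    if c.tp + c.fp + c.fn == 0:
        return 1.0
    return 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)


def iou(c: ConfusionCounts) -> float:
    """Foreground intersection over union."""
    if c.tp + c.fp + c.fn == 0:
        return 1.0
    return c.tp / (c.tp + c.fp + c.fn)


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of pixels predicted correctly."""
    if c.total == 0:
        raise ValueError("accuracy of zero-size masks is undefined")
    return (c.tp + c.tn) / c.total


def evaluate_masks(pred_masks, truth_masks, aggregate: str = "macro") -> dict:
    """Score a sequence of mask pairs.

    ``macro`` averages per-image scores; ``micro`` pools confusion counts
    over the whole set first.  Returns per-image rows plus the aggregate.
    """
    if aggregate not in ("macro", "micro"):
        raise ValueError("aggregate must be 'macro' or 'micro'")
    pred_masks, truth_masks = list(pred_masks), list(truth_masks)
    if len(pred_masks) != len(truth_masks):
        raise ValueError("prediction and truth sets differ in length")
    if not pred_masks:
        raise ValueError("cannot evaluate an empty mask set")
    rows = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for i, (p, t) in enumerate(zip(pred_masks, truth_masks)):
        c = confusion(p, t)
        pooled = pooled + c
        rows.append({"image": i, "f1": f1(c), "iou": iou(c),
                     "accuracy": accuracy(c)})
    if aggregate == "macro":
        agg = {k: float(np.mean([r[k] for r in rows]))
               for k in ("f1", "iou", "accuracy")}
    else:
        agg = {"f1": f1(pooled), "iou": iou(pooled),
               "accuracy": accuracy(pooled)}
    return {"per_image": rows, "aggregate": agg, "aggregation": aggregate}


def write_report(report: dict, path) -> None:
    """Write an evaluation report as CSV (per image) or JSON (full)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(report, indent=2))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["image", "f1", "iou", "accuracy"])
        writer.writeheader()
        for row in report["per_image"]:
            writer.writerow(row)
        writer.writerow({"image": f"aggregate_{report['aggregation']}",
                         **report["aggregate"]})
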