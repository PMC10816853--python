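"""Evaluation metrics for binary mass segmentation.

Per-image confusion counts feed four complementary metrics:

* DSC = 2TP / (2TP + FP + FN) — overlap quality;
* ΔA  = |(TP+FP) − (TP+FN)| / (TP+FN) — relative area difference,
  agreement of predicted and true mass size (lower is better);
* Sensitivity = TP / (TP + FN) — miss rate complement, clinically the
  critical quantity;
* Accuracy = (TP+TN) / total — dominated by background, reported for
  completeness.

Degenerate images are handled by documented conventions: when both masks
are empty, DSC = sensitivity = 1 and ΔA = 0; when only the ground truth
is empty, DSC = 0 and sensitivity/ΔA are undefined and excluded from
their aggregate means.  Aggregation is an unweighted mean over images
(macro) by default, with pooled-pixel (micro) aggregation as an option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, DimensionError, DomainError
from .masks import validate_bin_mask

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "binarize",
           "compute_metrics", "evaluate_dataset"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def binarize(pred, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability mask into {0.0, 1.0}."""
    if not (0.0 < threshold < 1.0):
        raise DomainError("threshold must lie in (0, 1)")
    return (np.asarray(pred, dtype=float) >= threshold).astype(float)


def confusion(pred_bin, gt) -> ConfusionCounts:
    """Exact pixel tallies of a binarized prediction against ground truth."""
    p = validate_bin_mask(pred_bin)
    y = validate_bin_mask(gt)
    if p.shape != y.shape:
        raise DimensionError(f"mask shapes differ: {p.shape} vs {y.shape}")
    tp = int(((p == 1) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    return ConfusionCounts(tp, tn, fp, fn)


def compute_metrics(c: ConfusionCounts) -> dict:
    """DSC, ΔA, sensitivity and accuracy from confusion counts.

    Undefined quantities (empty ground truth with non-empty prediction)
    are returned as ``None`` so aggregation can exclude them.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    if tp + fn == 0:               # empty ground truth
        if fp == 0:                # both empty: perfect by convention
            return {"dsc": 1.0, "delta_a": 0.0, "sensitivity": 1.0, "accuracy": 1.0}
        return {"dsc": 0.0, "delta_a": None, "sensitivity": None,
                "accuracy": (tp + tn) / c.total}
    dsc = 2.0 * tp / (2.0 * tp + fp + fn)
    delta_a = abs((tp + fp) - (tp + fn)) / (tp + fn)
    sensitivity = tp / (tp + fn)
    accuracy = (tp + tn) / c.total
    return {"dsc": dsc, "delta_a": delta_a,
            "sensitivity": sensitivity, "accuracy": accuracy}


_METRIC_KEYS = ("dsc", "delta_a", "sensitivity", "accuracy")


@dataclass
class MetricReport:
    """Aggregated metrics plus the per-image records they came from."""

    dsc: float
    delta_a: float
    sensitivity: float
    accuracy: float
    per_image: list = field(default_factory=list)
    aggregation: str = "mean_of_images"

    def summary(self, scale: float = 100.0) -> dict:
        """Aggregates on the ×100 scale used in results tables."""
        return {k: getattr(self, k) * scale for k in _METRIC_KEYS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_image)

    def to_json(self) -> str:
        return json.dumps({"aggregation": self.aggregation,
                           "n_images": len(self.per_image),
                           **{k: getattr(self, k) for k in _METRIC_KEYS},
                           "scaled_x100": self.summary()}, indent=2)


def evaluate_dataset(pred_masks, gt_masks, threshold: float = 0.5,
                     aggregation: str = "macro", sample_ids=None) -> MetricReport:
    """Binarize predictions, score each image, and aggregate.

    macro: unweighted mean over images of each defined per-image metric;
    micro: metrics of the pooled pixel-level confusion counts.
    """
    pred_masks, gt_masks = list(pred_masks), list(gt_masks)
    if len(pred_masks) != len(gt_masks):
        raise DataError(
            f"{len(pred_masks)} predictions vs {len(gt_masks)} ground truths")
    if not pred_masks:
        raise DataError("cannot evaluate an empty dataset")
    if aggregation not in ("macro", "micro"):
        raise DataError(f"unknown aggregation {aggregation!r}")
    ids = sample_ids if sample_ids is not None else list(range(len(pred_masks)))
    records, pooled = [], ConfusionCounts(0, 0, 0, 0)
    for sid, pred, gt in zip(ids, pred_masks, gt_masks):
        c = confusion(binarize(pred, threshold), gt)
        pooled = pooled + c
        records.append({"sample_id": sid, "tp": c.tp, "tn": c.tn,
                        "fp": c.fp, "fn": c.fn, **compute_metrics(c)})
    if aggregation == "micro":
        agg = compute_metrics(pooled)
        agg = {k: (v if v is not None else float("nan")) for k, v in agg.items()}
    else:
        agg = {}
        for key in _METRIC_KEYS:
            vals = [r[key] for r in records if r[key] is not None]
            agg[key] = float(np.mean(vals)) if vals else float("nan")
    return MetricReport(per_image=records,
                        aggregation="mean_of_images" if aggregation == "macro"
                        else "pooled_pixels", **agg)
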