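"""Pixel-level evaluation: confusion counts, the metric suite, PR/ROC
curves with AUC, and per-fold aggregation.

MP (mask value 255) is the positive class. The mean Jaccard and mean Dice
are unweighted averages of the two class-specific values, where the non-MP
class value is computed on the role-swapped confusion quadruple
(TP<->TN, FP<->FN).

Degenerate denominators (a class empty in both prediction and reference)
yield metric 1; mismatched emptiness yields 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .slide_io import MP

_CURVE_GRID = np.arange(256) / 255.0


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def swapped(self) -> "ConfusionCounts":
        """Role-swap so the non-MP class becomes the positive class."""
        return ConfusionCounts(TP=self.TN, TN=self.TP, FP=self.FN, FN=self.FP)


METRIC_FIELDS = [
    "jaccard_MP",
    "jaccard_nonMP",
    "mean_jaccard",
    "dice_MP",
    "dice_nonMP",
    "mean_dice",
    "pixel_accuracy",
    "precision",
    "recall",
    "specificity",
    "f1",
]


def confusion_counts(prediction: np.ndarray, reference: np.ndarray) -> ConfusionCounts:
    """Pixel-level TP/TN/FP/FN with MP (255) as the positive class."""
    if prediction.shape != reference.shape:
        raise ValueError("prediction/reference shape mismatch")
    pred_pos = prediction == MP
    ref_pos = reference == MP
    return ConfusionCounts(
        TP=int(np.count_nonzero(pred_pos & ref_pos)),
        TN=int(np.count_nonzero(~pred_pos & ~ref_pos)),
        FP=int(np.count_nonzero(pred_pos & ~ref_pos)),
        FN=int(np.count_nonzero(~pred_pos & ref_pos)),
    )


def _ratio(num: int, den: int) -> float:
    # empty class in both prediction and reference -> perfect agreement
    return 1.0 if den == 0 else num / den


def metric_suite(c: ConfusionCounts) -> dict[str, float]:
    """The seven-metric pixel-level report from one confusion quadruple.

    Jaccard = TP/(TP+FP+FN); Dice = 2TP/(2TP+FP+FN);
    accuracy = (TP+TN)/total; precision = TP/(TP+FP);
    recall = TP/(TP+FN); specificity = TN/(TN+FP);
    F1 = harmonic mean of precision and recall.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    s = c.swapped()
    precision = _ratio(c.TP, c.TP + c.FP)
    recall = _ratio(c.TP, c.TP + c.FN)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    report = {
        "jaccard_MP": _ratio(c.TP, c.TP + c.FP + c.FN),
        "jaccard_nonMP": _ratio(s.TP, s.TP + s.FP + s.FN),
        "dice_MP": _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
        "dice_nonMP": _ratio(2 * s.TP, 2 * s.TP + s.FP + s.FN),
        "pixel_accuracy": (c.TP + c.TN) / c.total,
        "precision": precision,
        "recall": recall,
        "specificity": _ratio(c.TN, c.TN + c.FP),
        "f1": f1,
    }
    report["mean_jaccard"] = (report["jaccard_MP"] + report["jaccard_nonMP"]) / 2
    report["mean_dice"] = (report["dice_MP"] + report["dice_nonMP"]) / 2
    return {k: report[k] for k in METRIC_FIELDS}


def evaluate_mask(prediction: np.ndarray, reference: np.ndarray) -> dict[str, float]:
    """Convenience: confusion counts then metric suite."""
    return metric_suite(confusion_counts(prediction, reference))


@dataclass
class CurveResult:
    points: np.ndarray  # (n, 2) of (x, y)
    auc: float
    kind: str


def curve_and_auc(heatmap: np.ndarray, reference: np.ndarray, kind: str) -> CurveResult:
    """PR or ROC curve over the 256-level threshold grid, AUC by trapezoid.

    ROC points are (FPR, TPR); PR points are (recall, precision) with the
    precision-1 convention at the recall-0 endpoint.
    """
    if kind not in ("PR", "ROC"):
        raise ValueError(f"curve kind must be PR or ROC, got {kind!r}")
    pos = np.sort(heatmap[reference == MP].ravel())
    neg = np.sort(heatmap[reference != MP].ravel())
    if pos.size == 0 or neg.size == 0:
        raise ValueError("reference contains a single class; curve undefined")
    # sweep thresholds from high to low so x is non-decreasing along the curve
    grid = _CURVE_GRID[::-1]
    tp = pos.size - np.searchsorted(pos, grid, side="left")
    fp = neg.size - np.searchsorted(neg, grid, side="left")
    tpr = tp / pos.size
    fpr = fp / neg.size
    if kind == "ROC":
        x = np.concatenate([[0.0], fpr, [1.0]])
        y = np.concatenate([[0.0], tpr, [1.0]])
    else:
        precision = np.where(tp + fp == 0, 1.0, tp / np.maximum(tp + fp, 1))
        x = np.concatenate([[0.0], tpr])
        y = np.concatenate([[1.0], precision])
    auc = float(np.trapezoid(y, x))
    return CurveResult(points=np.column_stack([x, y]), auc=auc, kind=kind)


def aggregate_folds(reports: list[dict[str, float]]) -> pd.DataFrame:
    """Per-fold rows plus a mean and an std summary row.

    Input is one metric report per fold (each typically the average over
    that fold's test images).
    """
    if not reports:
        raise ValueError("no fold reports to aggregate")
    df = pd.DataFrame(reports)
    df.insert(0, "fold", range(1, len(reports) + 1))
    mean_row = df.drop(columns="fold").mean()
    std_row = df.drop(columns="fold").std(ddof=0)
    summary = pd.DataFrame([mean_row, std_row])
    summary.insert(0, "fold", ["mean", "std"])
    return pd.concat([df.astype({"fold": object}), summary], ignore_index=True)


def mean_report(reports: list[dict[str, float]]) -> dict[str, float]:
    """Unweighted per-metric mean across image-level reports."""
    df = pd.DataFrame(reports)
    return df.mean().to_dict()
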