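"""Detection matching and counting metrics with per-stage reporting.

Detections are matched to ground-truth tip boxes greedily in decreasing
IoU order, one-to-one; a match with IoU above 0.5 is a true positive,
unmatched detections are false positives and unmatched ground truths false
negatives.  Counting accuracy over a set of images uses the per-image tip
counts: MAE, RMSE and the coefficient of determination

    MAE  = (1/n) sum |y_i - yhat_i|
    RMSE = sqrt((1/n) sum (y_i - yhat_i)^2)
    R^2  = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2

Metrics with a zero denominator are reported as ``None`` rather than
raising.  Per-stage reports bin images by the integer part of their Haun
stage, clamped to {1, 2, 3, 4} — the seedling window before tillering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EvalCounts",
    "CountSeries",
    "EvalReport",
    "iou",
    "match_detections",
    "precision_recall",
    "count_metrics",
    "per_stage_report",
]

Box = tuple[float, float, float, float]  # (x, y, w, h)


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class CountSeries:
    """Per-image true and predicted tip counts with their Haun stages."""

    y: list[float]
    y_hat: list[float]
    stage: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.y) != len(self.y_hat):
            raise ValueError("y and y_hat must have equal length")
        if self.stage is not None and len(self.stage) != len(self.y):
            raise ValueError("stage must match series length")
        if any(v < 0 for v in self.y) or any(v < 0 for v in self.y_hat):
            raise ValueError("counts must be non-negative")


@dataclass
class EvalReport:
    """Overall and per-stage detection/counting metrics."""

    counts: EvalCounts
    precision: float | None
    recall: float | None
    mae: float | None
    rmse: float | None
    r2: float | None
    per_stage: dict[int, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp, "fp": self.counts.fp, "fn": self.counts.fn,
            "precision": self.precision, "recall": self.recall,
            "mae": self.mae, "rmse": self.rmse, "r2": self.r2,
            "per_stage": self.per_stage,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_csv(self, path) -> None:
        rows = [{"stage": "overall", "tp": self.counts.tp, "fp": self.counts.fp,
                 "fn": self.counts.fn, "precision": self.precision,
                 "recall": self.recall, "mae": self.mae, "rmse": self.rmse,
                 "r2": self.r2}]
        for s, m in sorted(self.per_stage.items()):
            rows.append({"stage": s, **m})
        pd.DataFrame(rows).to_csv(path, index=False)


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection-over-union of two axis-aligned (x, y, w, h) boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("boxes must have positive area")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def match_detections(
    det_boxes: list[Box],
    gt_boxes: list[Box],
    iou_threshold: float = 0.5,
) -> tuple[EvalCounts, list[tuple[int, int, float]]]:
    """Greedy one-to-one matching in decreasing IoU order.

    Returns the TP/FP/FN counts and the matched (det_index, gt_index, iou)
    pairs.  A detection matches at most one ground truth and vice versa;
    only pairs with IoU strictly above the threshold count as TP.
    """
    pairs = []
    for i, db in enumerate(det_boxes):
        for j, gb in enumerate(gt_boxes):
            v = iou(db, gb)
            if v > iou_threshold:
                pairs.append((v, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_d: set[int] = set()
    used_g: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for v, i, j in pairs:
        if i in used_d or j in used_g:
            continue
        used_d.add(i)
        used_g.add(j)
        matches.append((i, j, v))
    tp = len(matches)
    return EvalCounts(tp=tp, fp=len(det_boxes) - tp, fn=len(gt_boxes) - tp), matches


def precision_recall(counts: EvalCounts) -> tuple[float | None, float | None]:
    """p = TP/(TP+FP), r = TP/(TP+FN); None where the denominator is zero."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    return p, r


def count_metrics(series: CountSeries) -> tuple[float | None, float | None, float | None]:
    """(MAE, RMSE, R^2) of predicted vs true per-image counts.

    R^2 is the standard coefficient of determination and is ``None`` when
    the true counts have zero variance (or fewer than two points).
    """
    y = np.asarray(series.y, dtype=float)
    yh = np.asarray(series.y_hat, dtype=float)
    if len(y) == 0:
        return None, None, None
    err = y - yh
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if len(y) < 2 or ss_tot <= 0:
        return mae, rmse, None
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return mae, rmse, r2


def _stage_bin(stage: float) -> int:
    return int(np.clip(np.floor(stage), 1, 4))


def per_stage_report(
    series: CountSeries, counts_per_image: list[EvalCounts]
) -> EvalReport:
    """Overall metrics plus a breakdown by development-stage bin {1..4}.

    Detection counts are summed within each bin; counting metrics are
    recomputed on the bin's per-image count series.  Empty bins are omitted.
    """
    if len(counts_per_image) != len(series.y):
        raise ValueError("counts_per_image must match series length")
    total = EvalCounts()
    for c in counts_per_image:
        total = total + c
    p, r = precision_recall(total)
    mae, rmse, r2 = count_metrics(series)
    report = EvalReport(counts=total, precision=p, recall=r,
                        mae=mae, rmse=rmse, r2=r2)
    if series.stage is None:
        return report
    bins: dict[int, list[int]] = {}
    for idx, s in enumerate(series.stage):
        bins.setdefault(_stage_bin(s), []).append(idx)
    for b, idxs in sorted(bins.items()):
        sub = CountSeries(
            y=[series.y[i] for i in idxs],
            y_hat=[series.y_hat[i] for i in idxs],
        )
        subtotal = EvalCounts()
        for i in idxs:
            subtotal = subtotal + counts_per_image[i]
        sp, sr = precision_recall(subtotal)
        smae, srmse, sr2 = count_metrics(sub)
        report.per_stage[b] = {
            "tp": subtotal.tp, "fp": subtotal.fp, "fn": subtotal.fn,
            "precision": sp, "recall": sr,
            "mae": smae, "rmse": srmse, "r2": sr2,
            "n_images": len(idxs),
        }
    return report
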