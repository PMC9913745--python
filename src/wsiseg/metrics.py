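"""Segmentation metrics: area-based Dice and IoU, Hausdorff distance.

TP/FP/FN are pixel-count areas per class, computed over non-ignored
pixels only:

    Dice = 2 TP / ((TP + FP) + (TP + FN))
    IoU  = TP / (TP + FP + FN)

(the two are linked by IoU = Dice / (2 - Dice)). Boundary disagreement
is measured by the undirected Hausdorff distance between the ground-
truth and predicted pixel sets of a class,

    H(A, B) = max( h(A, B), h(B, A) ),   h(A, B) = max_a min_b ||a - b||,

reported in pixels (optionally scaled by a physical pixel spacing). A
metric is *undefined* (NaN) when its inputs are degenerate — all three
areas zero, or an empty point set — and undefined entries are excluded
from averages.

Dataset aggregation is "micro" by default: areas are pooled over all
images per class before Dice/IoU are formed (stable for rare classes);
"macro" averages per-image scores instead. Hausdorff is always
computed per image and averaged over the images where it is defined.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .labels import CLASS_NAMES, N_CLASSES

__all__ = ["ConfusionAreas", "MetricsReport", "confusion_areas", "dice",
           "iou", "directed_hausdorff", "hausdorff", "points_of_class",
           "evaluate_dataset"]


@dataclass(frozen=True)
class ConfusionAreas:
    """Pixel-count areas for one class."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("areas must be non-negative")

    def __add__(self, other: "ConfusionAreas") -> "ConfusionAreas":
        return ConfusionAreas(self.tp + other.tp, self.fp + other.fp,
                              self.fn + other.fn)


def confusion_areas(pred: np.ndarray, gt: np.ndarray,
                    ignore: np.ndarray | None,
                    class_index: int) -> ConfusionAreas:
    """TP/FP/FN pixel areas for ``class_index`` over non-ignored pixels."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"pred {pred.shape} and gt {gt.shape} shapes differ")
    valid = np.ones(pred.shape, bool)
    if ignore is not None:
        ignore = np.asarray(ignore, bool)
        if ignore.shape != pred.shape:
            raise ValueError("ignore mask shape differs from labels")
        valid = ~ignore
    p = (pred == class_index) & valid
    g = (gt == class_index) & valid
    return ConfusionAreas(tp=int((p & g).sum()), fp=int((p & ~g).sum()),
                          fn=int((~p & g).sum()))


def dice(c: ConfusionAreas) -> float:
    """2 TP / ((TP+FP) + (TP+FN)); NaN when all areas are zero."""
    denom = (c.tp + c.fp) + (c.tp + c.fn)
    if denom == 0:
        return math.nan
    return 2.0 * c.tp / denom


def iou(c: ConfusionAreas) -> float:
    """TP / (TP+FP+FN); NaN when all areas are zero."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return math.nan
    return c.tp / denom


def points_of_class(label_map: np.ndarray, class_index: int,
                    ignore: np.ndarray | None = None) -> np.ndarray:
    """(n, 2) array of (row, col) pixels carrying ``class_index``."""
    sel = np.asarray(label_map) == class_index
    if ignore is not None:
        sel &= ~np.asarray(ignore, bool)
    return np.argwhere(sel)


def directed_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """max over a in A of the Euclidean distance to its nearest b in B.

    Not symmetric. NaN if either set is empty.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return math.nan
    d, _ = cKDTree(b).query(a, k=1)
    return float(np.max(d))


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Undirected (symmetric) Hausdorff distance: the max of the two
    directed distances. NaN if either set is empty."""
    d_ab = directed_hausdorff(a, b)
    d_ba = directed_hausdorff(b, a)
    if math.isnan(d_ab) or math.isnan(d_ba):
        return math.nan
    return max(d_ab, d_ba)


@dataclass
class MetricsReport:
    """Per-class and average Dice/IoU/Hausdorff, report-table shaped."""

    per_class: dict[str, dict[str, float]]
    average: dict[str, float]
    aggregation: str
    hausdorff_undefined_images: dict[str, int]
    spacing: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = {**self.per_class, "average": self.average}
        return pd.DataFrame(rows).T[["dice", "iou", "hausdorff"]]

    def write(self, path_prefix) -> None:
        path_prefix = Path(path_prefix)
        path_prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(f"{path_prefix}.csv")
        payload = {"per_class": self.per_class, "average": self.average,
                   "aggregation": self.aggregation,
                   "hausdorff_undefined_images":
                       self.hausdorff_undefined_images,
                   "spacing": self.spacing}
        Path(f"{path_prefix}.json").write_text(json.dumps(payload, indent=2))


def _nanmean(values) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return sum(vals) / len(vals) if vals else math.nan


def evaluate_dataset(predictions, ground_truths, ignores=None,
                     aggregation: str = "micro",
                     spacing: float | None = None) -> MetricsReport:
    """Score aligned lists of merged label maps.

    ``aggregation`` picks how Dice/IoU pool over images: "micro" sums
    areas first, "macro" averages per-image values. Per image and class,
    Hausdorff is skipped (not counted) when the class is absent from
    both maps, and undefined (flagged, excluded from the mean) when
    absent from exactly one.
    """
    preds = list(predictions)
    gts = list(ground_truths)
    if not preds:
        raise ValueError("empty prediction list")
    if len(preds) != len(gts):
        raise ValueError("prediction and ground-truth counts differ")
    igns = list(ignores) if ignores is not None else [None] * len(preds)
    if aggregation not in ("micro", "macro"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    per_class: dict[str, dict[str, float]] = {}
    undefined: dict[str, int] = {}
    for ci, cname in enumerate(CLASS_NAMES[:N_CLASSES]):
        areas = [confusion_areas(p, g, m, ci)
                 for p, g, m in zip(preds, gts, igns)]
        if aggregation == "micro":
            total = ConfusionAreas(0, 0, 0)
            for a in areas:
                total = total + a
            d, j = dice(total), iou(total)
        else:
            d = _nanmean([dice(a) for a in areas])
            j = _nanmean([iou(a) for a in areas])
        hds = []
        n_undefined = 0
        for p, g, m in zip(preds, gts, igns):
            pa = points_of_class(g, ci, m)
            pb = points_of_class(p, ci, m)
            if pa.shape[0] == 0 and pb.shape[0] == 0:
                continue                       # class absent everywhere: skip
            if pa.shape[0] == 0 or pb.shape[0] == 0:
                n_undefined += 1               # absent on one side: flagged
                continue
            h = hausdorff(pa, pb)
            hds.append(h if spacing is None else h * spacing)
        per_class[cname] = {"dice": d, "iou": j, "hausdorff": _nanmean(hds)}
        undefined[cname] = n_undefined
    average = {m: _nanmean([per_class[c][m] for c in per_class])
               for m in ("dice", "iou", "hausdorff")}
    return MetricsReport(per_class=per_class, average=average,
                         aggregation=aggregation,
                         hausdorff_undefined_images=undefined,
                         spacing=spacing)
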