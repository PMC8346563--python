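"""Exudate-level and image-level evaluation of box detections.

Detections are rectangles, so lesion-level scoring works on *filled*
boxes: each ground-truth object contributes the pixels of its tight
bounding box, each detection the pixels of its predicted box, and the
accounting runs over pixels of those filled rectangles.

Exudate level (strict mode): a ground-truth object counts as *found*
when some detection box covers strictly more than ``overlap_min``
(default 20%) of the object's filled-box area. Found objects contribute
their box pixels as true positives; missed objects contribute false
negatives; detections that qualify for no object contribute false
positives; everything else is true negative. A coarse-annotation mode
(``any_overlap``) instead accepts a single shared pixel, for datasets
whose expert markings are deliberately oversized regions.

Image level: an image is called positive when the maximum per-patch
detection score reaches a threshold (default 0.9); the same confusion
metrics then run over image counts, and an ROC/AUC summarises the score
ranking.

Metric definitions: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
PPV = TP/(TP+FP), accuracy = (TP+TN)/total, FPR = FP/(FP+TN),
FNR = FN/(FN+TP), and F1 = 2*sensitivity*PPV/(sensitivity+PPV). Fold
aggregation reports mean +/- standard deviation per metric, averaging F1
over folds rather than recomputing it from averaged sensitivity and PPV.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .annotations import ExudateObject
from .detector import Detection
from .geometry import BoundingBox

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "f1", "ppv", "fpr", "fnr")


@dataclass(frozen=True)
class PixelCounts:
    """TP/FP/FN/TN pixel (or image) tallies."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """The seven derived metrics; None marks an undefined denominator."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    f1: Optional[float]
    ppv: Optional[float]
    fpr: Optional[float]
    fnr: Optional[float]

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class ObjectStatus:
    """Per-object match outcome for one evaluated image."""

    found: List[bool]  # per ground-truth object
    best_overlap: List[float]  # best overlap fraction per ground-truth object
    matched: List[bool]  # per detection


def fill_boxes(boxes: Sequence[BoundingBox], shape: Tuple[int, int]) -> np.ndarray:
    """Rasterise the union of boxes into a binary (H, W) array."""
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    for b in boxes:
        if not b.within(w, h):
            raise ValueError(f"box {b} exceeds the image shape {(h, w)}")
        out[b.y0 : b.y1, b.x0 : b.x1] = True
    return out


def match_exudate_level(
    gt_objects: Sequence[ExudateObject],
    detections: Sequence[Detection],
    shape: Tuple[int, int],
    overlap_min: float = 0.2,
    mode: str = "strict",
    denominator: str = "gt",
) -> Tuple[PixelCounts, ObjectStatus]:
    """Pixel bookkeeping of filled-box overlap between truth and detections.

    overlap fractions divide the box intersection by the ground-truth
    filled-box area (``denominator="gt"``) or by the smaller of the two
    areas (``denominator="min"``). In strict mode an object is found iff
    its best overlap strictly exceeds ``overlap_min``; in ``any_overlap``
    mode one shared pixel suffices. The four counts always sum to the
    pixel count of ``shape``.
    """
    if not (0.0 <= overlap_min < 1.0):
        raise ValueError("overlap_min must lie in [0, 1)")
    if mode not in ("strict", "any_overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    if denominator not in ("gt", "min"):
        raise ValueError(f"unknown denominator {denominator!r}")
    h, w = shape
    for obj in gt_objects:
        if not obj.box.within(w, h):
            raise ValueError(f"ground-truth box {obj.box} exceeds shape {(h, w)}")
    for det in detections:
        if not det.box.within(w, h):
            raise ValueError(f"detection box {det.box} exceeds shape {(h, w)}")

    found: List[bool] = []
    best_overlap: List[float] = []
    matched = [False] * len(detections)
    for obj in gt_objects:
        best = 0.0
        any_hit = False
        for j, det in enumerate(detections):
            inter = obj.box.intersection_area(det.box)
            if inter == 0:
                continue
            denom = obj.box.area if denominator == "gt" else min(obj.box.area, det.box.area)
            frac = inter / denom
            best = max(best, frac)
            hit = frac > overlap_min if mode == "strict" else True
            if hit:
                any_hit = True
                matched[j] = True
        found.append(any_hit)
        best_overlap.append(best)

    tp_mask = fill_boxes([o.box for o, f in zip(gt_objects, found) if f], shape)
    fn_mask = fill_boxes([o.box for o, f in zip(gt_objects, found) if not f], shape)
    fn_mask &= ~tp_mask
    fp_mask = fill_boxes([d.box for d, m in zip(detections, matched) if not m], shape)
    fp_mask &= ~(tp_mask | fn_mask)
    tp = int(tp_mask.sum())
    fn = int(fn_mask.sum())
    fp = int(fp_mask.sum())
    tn = h * w - tp - fn - fp
    return (
        PixelCounts(tp=tp, fp=fp, fn=fn, tn=tn),
        ObjectStatus(found=found, best_overlap=best_overlap, matched=matched),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(counts: PixelCounts) -> MetricSet:
    """Derive the seven metrics; undefined denominators yield None."""
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    acc = _ratio(counts.tp + counts.tn, counts.total)
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    fpr = _ratio(counts.fp, counts.fp + counts.tn)
    fnr = _ratio(counts.fn, counts.fn + counts.tp)
    if sens is None or ppv is None or (sens + ppv) == 0:
        f1 = None
    else:
        f1 = 2 * sens * ppv / (sens + ppv)
    return MetricSet(
        sensitivity=sens, specificity=spec, accuracy=acc, f1=f1, ppv=ppv, fpr=fpr, fnr=fnr
    )


def image_level_decision(per_patch_scores: Sequence[float], tau: float = 0.9) -> bool:
    """Call the image positive iff any patch score reaches tau (>=)."""
    scores = np.asarray(per_patch_scores, dtype=np.float64)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("patch scores must lie in [0, 1]")
    if scores.size == 0:
        return False
    return bool(scores.max() >= tau)


def image_level_metrics(
    decisions: Sequence[bool], labels: Sequence[bool]
) -> Tuple[PixelCounts, MetricSet]:
    """Confusion counts and metrics over whole images."""
    d = np.asarray(decisions, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if d.size == 0 or d.shape != y.shape:
        raise ValueError("decisions and labels must be equal-length and non-empty")
    counts = PixelCounts(
        tp=int((d & y).sum()),
        fp=int((d & ~y).sum()),
        fn=int((~d & y).sum()),
        tn=int((~d & ~y).sum()),
    )
    return counts, compute_metrics(counts)


def roc_auc(image_scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve of image scores against labels.

    Equals the probability that a random positive image outscores a
    random negative one, counting ties as one half.
    """
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(y, np.asarray(image_scores, dtype=np.float64)))


def roc_points(
    image_scores: Sequence[float], labels: Sequence[bool]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) of the ROC sweep, for plotting or export."""
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("roc_points needs both classes present")
    fpr, tpr, thr = roc_curve(y, np.asarray(image_scores, dtype=np.float64))
    return fpr, tpr, thr


def relative_change(before: float, after: float) -> float:
    """Percent change 100 * (after - before) / before; negative = reduction."""
    if before <= 0:
        raise ValueError("relative_change requires before > 0")
    return 100.0 * (after - before) / before


def aggregate_folds(
    fold_metrics: Sequence[MetricSet], ddof: int = 1
) -> Dict[str, Tuple[float, float]]:
    """Per-metric mean and standard deviation over cross-validation folds.

    Uses the sample standard deviation by default (ddof=1, appropriate
    for the usual small fold counts). F1 is averaged across folds — not
    recomputed from the averaged sensitivity and PPV, which would give a
    different (and misleading) number. Folds where a metric is undefined
    are dropped for that metric.
    """
    if len(fold_metrics) == 0:
        raise ValueError("need at least one fold")
    out: Dict[str, Tuple[float, float]] = {}
    for name in METRIC_NAMES:
        vals = [getattr(m, name) for m in fold_metrics if getattr(m, name) is not None]
        if not vals:
            continue
        arr = np.asarray(vals, dtype=np.float64)
        sd = float(arr.std(ddof=ddof)) if arr.size > ddof else 0.0
        out[name] = (float(arr.mean()), sd)
    return out
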