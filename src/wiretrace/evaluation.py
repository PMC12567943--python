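"""Tolerance-based evaluation measures for thin-structure segmentation.

Exact-overlap measures (Dice, IOU) collapse for 1-px-wide structures: a
perfect 1-px curve annotated one pixel off everywhere scores Dice = IOU = 0.
The measures here therefore also include distance-tolerant precision/recall
(a predicted pixel counts as correct if a ground-truth pixel lies within
``tol`` px, and vice versa; default tolerance 3 px), the average Hausdorff
distance (mean of the two directed average nearest-neighbor distances), and,
for localization, the average number of curves per image.

Distances are Euclidean, computed with the exact distance transform.
Localization scoring thins the ground-truth mask first (so thick annotations
are compared centerline-to-centerline) and rasterizes the predicted curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.draw import line as _draw_line

Curve = np.ndarray


@dataclass
class SegMetrics:
    """Segmentation scores: precision/recall/f1 in percent, dice/iou in [0, 1]."""

    precision: float
    recall: float
    f1: float
    dice: float
    iou: float
    ahd: float | None
    undefined_precision: bool = False
    undefined_recall: bool = False


@dataclass
class LocMetrics(SegMetrics):
    avg_curves: float = 0.0


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def tolerance_pr(
    pred: np.ndarray, gt: np.ndarray, tol: float = 3.0
) -> tuple[float, float, float]:
    """Distance-tolerant precision, recall and F1, all in percent.

    precision = % of predicted positives with a GT positive within Euclidean
    distance ``tol``; recall = % of GT positives with a predicted positive
    within ``tol``.  An empty prediction (or empty GT) makes precision (or
    recall) undefined and reported as 0.
    """
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.any():
        dist_to_gt = distance_transform_edt(~gt) if gt.any() else np.full(gt.shape, np.inf)
        precision = 100.0 * float(np.mean(dist_to_gt[pred] <= tol))
    else:
        precision = 0.0
    if gt.any():
        dist_to_pred = distance_transform_edt(~pred) if pred.any() else np.full(pred.shape, np.inf)
        recall = 100.0 * float(np.mean(dist_to_pred[gt] <= tol))
    else:
        recall = 0.0
    return precision, recall, _f1(precision, recall)


def dice_iou(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    """Exact set-overlap Dice 2|A^B|/(|A|+|B|) and Jaccard |A^B|/|AvB|.

    Both are 1 when both masks are empty (nothing to find, nothing found)
    and 0 when exactly one is empty.
    """
    a = np.asarray(pred).astype(bool)
    b = np.asarray(gt).astype(bool)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0, 1.0
    inter = int((a & b).sum())
    dice = 2.0 * inter / (na + nb)
    iou = inter / (na + nb - inter)
    return dice, iou


def ahd(pred: np.ndarray, gt: np.ndarray) -> float | None:
    """Average Hausdorff distance; None when either mask is empty (undefined)."""
    a = np.asarray(pred).astype(bool)
    b = np.asarray(gt).astype(bool)
    if not a.any() or not b.any():
        return None
    d_to_b = distance_transform_edt(~b)
    d_to_a = distance_transform_edt(~a)
    return 0.5 * (float(d_to_b[a].mean()) + float(d_to_a[b].mean()))


def rasterize_curves(
    curves: list[Curve], shape: tuple[int, int], fill_gaps: bool = False
) -> np.ndarray:
    """Burn curves into a binary mask.

    Consecutive stored points are already 8-adjacent within fragments; with
    ``fill_gaps`` any non-adjacent consecutive pair (a merge seam) is bridged
    by a straight line segment.
    """
    mask = np.zeros(shape, dtype=np.uint8)
    for curve in curves:
        c = np.asarray(curve)
        if len(c) == 0:
            continue
        inb = (c[:, 0] >= 0) & (c[:, 0] < shape[0]) & (c[:, 1] >= 0) & (c[:, 1] < shape[1])
        mask[c[inb, 0], c[inb, 1]] = 1
        if fill_gaps and len(c) > 1:
            jumps = np.flatnonzero(np.abs(np.diff(c, axis=0)).max(axis=1) > 1)
            for j in jumps:
                rr, cc = _draw_line(*c[j], *c[j + 1])
                keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
                mask[rr[keep], cc[keep]] = 1
    return mask


def segmentation_eval(pred: np.ndarray, gt: np.ndarray, tol: float = 3.0) -> SegMetrics:
    """All segmentation measures for one (prediction, ground truth) pair."""
    p, r, f = tolerance_pr(pred, gt, tol)
    d, i = dice_iou(pred, gt)
    return SegMetrics(
        precision=p,
        recall=r,
        f1=f,
        dice=d,
        iou=i,
        ahd=ahd(pred, gt),
        undefined_precision=not np.asarray(pred).astype(bool).any(),
        undefined_recall=not np.asarray(gt).astype(bool).any(),
    )


def localization_eval(
    curves: list[Curve],
    gt_mask: np.ndarray,
    tol: float = 3.0,
    fill_gaps: bool = False,
) -> LocMetrics:
    """Score predicted curves against a ground-truth mask.

    The GT mask is thinned to its centerline (idempotent on 1-px masks) so
    thick annotations are compared 1-px to 1-px; the curves are rasterized
    (optionally bridging merge seams).
    """
    from wiretrace.extraction import thin

    gt_thin = thin(gt_mask) if np.asarray(gt_mask).any() else np.asarray(gt_mask)
    pred = rasterize_curves(curves, np.asarray(gt_mask).shape, fill_gaps=fill_gaps)
    seg = segmentation_eval(pred, gt_thin, tol)
    return LocMetrics(**seg.__dict__, avg_curves=float(len(curves)))


def tolerance_sweep(
    pred: np.ndarray, gt: np.ndarray, tols: list[float] = (0, 1, 2, 3, 4)
) -> dict[float, float]:
    """F1 at each tolerance; non-decreasing in the tolerance by construction."""
    return {float(t): tolerance_pr(pred, gt, t)[2] for t in tols}


@dataclass
class MetricAggregate:
    """Per-image mean and std of each metric over a test set.

    Images with an empty prediction or empty GT are excluded from the AHD
    mean and counted in ``n_images_skipped_for_ahd``.
    """

    mean: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)
    n_images: int = 0
    n_images_skipped_for_ahd: int = 0


def aggregate(metrics: list[SegMetrics]) -> MetricAggregate:
    """Average per-image metrics across a test set."""
    agg = MetricAggregate(n_images=len(metrics))
    fields_num = ["precision", "recall", "f1", "dice", "iou"]
    if metrics and isinstance(metrics[0], LocMetrics):
        fields_num.append("avg_curves")
    for name in fields_num:
        vals = np.array([getattr(m, name) for m in metrics], dtype=float)
        agg.mean[name] = float(vals.mean())
        agg.std[name] = float(vals.std())
    ahds = np.array([m.ahd for m in metrics if m.ahd is not None], dtype=float)
    agg.n_images_skipped_for_ahd = len(metrics) - len(ahds)
    agg.mean["ahd"] = float(ahds.mean()) if len(ahds) else float("nan")
    agg.std["ahd"] = float(ahds.std()) if len(ahds) else float("nan")
    return agg
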