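"""Segmentation evaluation: Dice, 95th-percentile Hausdorff, voxel recall,
lesion-wise recall/F1, and median-size-stratified lesion recall.

Lesion-wise metrics operate on connected components (8-connectivity in 2D,
26 in 3D by default): a ground-truth lesion counts as detected iff at
least one predicted voxel overlaps it, and a predicted component with no
ground-truth overlap is a false positive.  The size-stratified recall
splits ground-truth lesions at the median component size, lesions of
exactly median size going to the "small" stratum.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

#: sentinel for metrics that are undefined on the given masks
UNDEFINED = float("nan")


@dataclass
class MetricsReport:
    dice: float
    h95: float
    recall: float
    lesion_recall: float
    lesion_f1: float
    recall_large: float
    recall_small: float
    median_lesion_size: float
    n_lesions_gt: int
    h95_defined: bool = True


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    return pred.astype(bool), gt.astype(bool)


def dice_score(pred: np.ndarray, gt: np.ndarray) -> float:
    """2|P∩G| / (|P|+|G|); both-empty convention: 1.0 (agreement on absence)."""
    p, g = _check_pair(pred, gt)
    denom = p.sum() + g.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, g).sum() / denom)


def voxel_recall(pred: np.ndarray, gt: np.ndarray) -> float:
    """|P∩G| / |G|; NaN when the ground truth is empty."""
    p, g = _check_pair(pred, gt)
    if g.sum() == 0:
        return UNDEFINED
    return float(np.logical_and(p, g).sum() / g.sum())


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Voxels of the mask that touch the outside (face connectivity)."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(mask.ndim, 1),
                                    border_value=0)
    return mask & ~eroded


def hausdorff95(pred: np.ndarray, gt: np.ndarray,
                spacing: tuple[float, ...] | None = None) -> tuple[float, bool]:
    """Symmetric 95th-percentile boundary-to-boundary Hausdorff distance.

    Returns (value, defined).  If either mask is empty the distance is
    undefined; the sentinel is the image diagonal length (in spacing
    units) with defined=False.
    """
    p, g = _check_pair(pred, gt)
    if spacing is None:
        spacing = (1.0,) * p.ndim
    sp = np.asarray(spacing, dtype=float)
    diag = float(np.linalg.norm(sp * np.asarray(p.shape)))
    if not p.any() or not g.any():
        return diag, False
    pb = np.argwhere(_boundary(p)) * sp
    gb = np.argwhere(_boundary(g)) * sp
    d_pg = cKDTree(gb).query(pb, k=1)[0]
    d_gp = cKDTree(pb).query(gb, k=1)[0]
    return float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95))), True


def _structure(ndim: int):
    # 8-connectivity in 2D, 26-connectivity in 3D
    return ndimage.generate_binary_structure(ndim, ndim)


def lesion_f1(pred: np.ndarray, gt: np.ndarray,
              connectivity=None) -> tuple[float, float, int, int]:
    """Component-wise detection: (lesion_recall, f1, n_detected, n_lesions_gt).

    Empty ground truth gives NaN recall; F1 is still defined through the
    false-positive count (1.0 only if the prediction is empty too).
    """
    p, g = _check_pair(pred, gt)
    st = connectivity if connectivity is not None else _structure(p.ndim)
    gl, ng = ndimage.label(g, structure=st)
    pl, npred = ndimage.label(p, structure=st)
    detected = 0
    for i in range(1, ng + 1):
        if p[gl == i].any():
            detected += 1
    fp = 0
    for j in range(1, npred + 1):
        if not g[pl == j].any():
            fp += 1
    fn = ng - detected
    recall = detected / ng if ng else UNDEFINED
    denom = 2 * detected + fp + fn
    f1 = (2 * detected / denom) if denom else 1.0
    return recall, f1, detected, ng


def size_stratified_recall(pred: np.ndarray, gt: np.ndarray,
                           connectivity=None) -> tuple[float, float, float]:
    """Per-stratum lesion recall around the median GT component size.

    Components with size <= median are "small"; the rest "large".  An
    empty stratum yields NaN.  Raises on empty ground truth.
    """
    p, g = _check_pair(pred, gt)
    st = connectivity if connectivity is not None else _structure(p.ndim)
    gl, ng = ndimage.label(g, structure=st)
    if ng == 0:
        raise ValueError("ground truth has no lesions; stratified recall undefined")
    sizes = ndimage.sum_labels(np.ones_like(gl), gl, index=range(1, ng + 1))
    median = float(np.median(sizes))
    hits = np.array([p[gl == i].any() for i in range(1, ng + 1)])
    small = sizes <= median
    large = ~small
    r_small = float(hits[small].mean()) if small.any() else UNDEFINED
    r_large = float(hits[large].mean()) if large.any() else UNDEFINED
    return r_large, r_small, median


def evaluate_pair(pred: np.ndarray, gt: np.ndarray,
                  spacing: tuple[float, ...] | None = None) -> MetricsReport:
    """All metrics for one (prediction, ground-truth) pair."""
    d = dice_score(pred, gt)
    h95, defined = hausdorff95(pred, gt, spacing)
    vr = voxel_recall(pred, gt)
    lr, f1, _, ng = lesion_f1(pred, gt)
    if ng:
        r_large, r_small, med = size_stratified_recall(pred, gt)
    else:
        r_large = r_small = med = UNDEFINED
    return MetricsReport(dice=d, h95=h95, recall=vr, lesion_recall=lr, lesion_f1=f1,
                         recall_large=r_large, recall_small=r_small,
                         median_lesion_size=med, n_lesions_gt=ng, h95_defined=defined)
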