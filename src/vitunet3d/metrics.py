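"""Evaluation metrics for volumetric segmentation masks.

Implements the seven-metric suite standard in brain-tumor segmentation:
overlap (DSC), boundary distances (HD95, MASD), voxel classification rates
(sensitivity, specificity, precision) and normalized surface dice (NSD),
together with the BraTS region grouping — whole tumor WT = labels {1,2,4},
tumor core TC = {1,4}, enhancing tumor ET = {4}.

Conventions (documented because the formulas leave them open):

* a *boundary* voxel is a mask voxel with at least one background voxel in
  its 6-neighborhood (volume borders count as background);
* distances are Euclidean in millimetres using the voxel spacing, computed
  with a distance transform;
* both masks empty -> DSC = 1, NSD = 1; distance metrics return NaN with a
  warning when either mask is empty; zero-denominator rates return 0 with a
  warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ConfusionCounts",
    "REGION_LABELS",
    "region_masks",
    "confusion_counts",
    "dsc",
    "hd95",
    "sensitivity",
    "specificity",
    "precision",
    "nsd",
    "masd",
    "boundary",
    "surface_distances",
    "evaluate_masks",
    "evaluate_labels",
]

VALID_LABELS = frozenset({0, 1, 2, 4})
REGION_LABELS = {"WT": (1, 2, 4), "TC": (1, 4), "ET": (4,)}
_SIX_NEIGHBORHOOD = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def region_masks(labels: np.ndarray) -> dict[str, np.ndarray]:
    """Group a {0,1,2,4} label volume into nested WT/TC/ET binary masks."""
    labels = np.asarray(labels)
    unknown = set(np.unique(labels)) - VALID_LABELS
    if unknown:
        raise ValueError(f"unknown label values: {sorted(unknown)}")
    return {name: np.isin(labels, vals) for name, vals in REGION_LABELS.items()}


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity 2|P∩Y| / (|P|+|Y|); 1.0 when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pred & truth).sum()) / denom


def boundary(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >= 1 background voxel in the 6-neighborhood."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    interior = ndimage.binary_erosion(mask, structure=_SIX_NEIGHBORHOOD,
                                      border_value=0)
    return mask & ~interior


def surface_distances(from_mask: np.ndarray, to_mask: np.ndarray,
                      spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Distances (mm) from each boundary voxel of one mask to the other's
    boundary surface."""
    b_from = boundary(from_mask)
    b_to = boundary(to_mask)
    dist_to = ndimage.distance_transform_edt(~b_to, sampling=spacing)
    return dist_to[b_from]


def _empty_sentinel(name: str) -> float:
    warnings.warn(f"{name}: empty mask, returning NaN", stacklevel=3)
    return float("nan")


def hd95(pred: np.ndarray, truth: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric 95th-percentile surface distance in mm."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if not pred.any() or not truth.any():
        return _empty_sentinel("hd95")
    d_pt = surface_distances(pred, truth, spacing)
    d_tp = surface_distances(truth, pred, spacing)
    return float(max(np.percentile(d_pt, 95), np.percentile(d_tp, 95)))


def masd(pred: np.ndarray, truth: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Mean absolute surface distance: symmetric average of mean nearest-
    surface distances, in mm."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if not pred.any() or not truth.any():
        return _empty_sentinel("masd")
    d_pt = surface_distances(pred, truth, spacing)
    d_tp = surface_distances(truth, pred, spacing)
    return float(0.5 * (d_tp.mean() + d_pt.mean()))


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, returning 0", stacklevel=3)
        return 0.0
    return num / den


def sensitivity(c: ConfusionCounts) -> float:
    """Recall TP / (TP + FN)."""
    return _rate(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    return _rate(c.tn, c.tn + c.fp, "specificity")


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    return _rate(c.tp, c.tp + c.fp, "precision")


def nsd(pred: np.ndarray, truth: np.ndarray, tolerance: float = 1.0,
        spacing=(1.0, 1.0, 1.0)) -> float:
    """Normalized surface dice at tolerance tau (mm).

    ``(|B_Y ∩ R_P| + |B_P ∩ R_Y|) / (|B_Y| + |B_P|)`` where ``R`` is the set
    of voxels within tau of the corresponding boundary.  Both masks empty
    -> 1.0; exactly one empty -> 0.0.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if not pred.any() and not truth.any():
        return 1.0
    if not pred.any() or not truth.any():
        return 0.0
    b_p, b_y = boundary(pred), boundary(truth)
    dist_p = ndimage.distance_transform_edt(~b_p, sampling=spacing)
    dist_y = ndimage.distance_transform_edt(~b_y, sampling=spacing)
    tol = tolerance + 1e-9
    hit_y = int((dist_p[b_y] <= tol).sum())
    hit_p = int((dist_y[b_p] <= tol).sum())
    return (hit_y + hit_p) / (int(b_y.sum()) + int(b_p.sum()))


def evaluate_masks(pred: np.ndarray, truth: np.ndarray,
                   spacing=(1.0, 1.0, 1.0), tolerance: float = 1.0
                   ) -> dict[str, float]:
    """All seven metrics for one binary region pair."""
    c = confusion_counts(pred, truth)
    return {
        "DSC": dsc(pred, truth),
        "HD95": hd95(pred, truth, spacing),
        "SE": sensitivity(c),
        "SP": specificity(c),
        "Pres": precision(c),
        "NSD": nsd(pred, truth, tolerance, spacing),
        "MASD": masd(pred, truth, spacing),
    }


def evaluate_labels(pred_labels: np.ndarray, true_labels: np.ndarray,
                    spacing=(1.0, 1.0, 1.0), tolerance: float = 1.0
                    ) -> pd.DataFrame:
    """Per-region metric report for a pair of {0,1,2,4} label volumes."""
    pred_regions = region_masks(pred_labels)
    true_regions = region_masks(true_labels)
    rows = {}
    for region in REGION_LABELS:
        rows[region] = evaluate_masks(pred_regions[region],
                                      true_regions[region], spacing, tolerance)
    report = pd.DataFrame(rows).T
    report.index.name = "region"
    return report
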