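"""Segmentation training objectives: focal, dice and their weighted hybrid.

All losses take per-voxel class probabilities ``P`` and (optionally
smoothed) one-hot targets ``Y`` laid out as ``(..., J)`` with the class axis
last; any leading shape is treated as the voxel index.  They accept either
plain numpy arrays (returning a float) or autograd tensors (returning a
scalar tensor usable for backpropagation).

Focal loss re-weights cross-entropy by ``alpha * (1 - P)^gamma`` so easy,
abundant voxels (background) contribute little and training concentrates on
hard tumor voxels.  Dice loss is one minus the soft overlap fraction
``2 sum(PY) / (sum(P^2) + sum(Y^2))`` accumulated over all voxels and
classes.  The hybrid is their weighted sum, by default an unweighted one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, no_grad

__all__ = [
    "LossWeights",
    "smooth_labels",
    "one_hot",
    "focal_loss",
    "dice_loss",
    "hybrid_loss",
]

_LOG_EPS = 1e-12
_DICE_SMOOTH = 1e-5


@dataclass(frozen=True)
class LossWeights:
    """Balance (alpha), focus (gamma) and component weights of the hybrid."""

    alpha: float = 0.25
    gamma: float = 2.0
    lam_dice: float = 1.0
    lam_focal: float = 1.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.lam_dice < 0 or self.lam_focal < 0 or (
                self.lam_dice == 0 and self.lam_focal == 0):
            raise ValueError("component weights must be >= 0 and not both 0")


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """Integer class grid -> (..., J) one-hot indicators."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError(f"labels outside [0, {num_classes})")
    return np.eye(num_classes, dtype=np.float64)[labels]


def smooth_labels(y: np.ndarray, eps: float) -> np.ndarray:
    """Label smoothing: one-hot targets relaxed toward the uniform simplex."""
    y = np.asarray(y, dtype=np.float64)
    j = y.shape[-1]
    return y * (1.0 - eps) + eps / j


def _check_pair(p, y):
    pd = p.data if isinstance(p, Tensor) else np.asarray(p)
    yd = y.data if isinstance(y, Tensor) else np.asarray(y)
    if pd.shape != yd.shape:
        raise ValueError(f"shape mismatch: P {pd.shape} vs Y {yd.shape}")
    if pd.min() < -1e-9 or pd.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.allclose(pd.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("per-voxel class probabilities must sum to 1")


def _eval(fn, p, y, *args):
    """Run ``fn`` on tensors; numpy in, float out; tensor in, tensor out."""
    tensor_in = isinstance(p, Tensor)
    pt = p if tensor_in else Tensor(np.asarray(p, dtype=np.float64))
    yt = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=np.float64))
    if tensor_in:
        return fn(pt, yt, *args)
    with no_grad():
        out = fn(pt, yt, *args)
    return float(out.data)


def focal_loss(p, y, alpha: float = 0.25, gamma: float = 2.0):
    """``-(1/I) sum_i sum_j alpha (1 - P_ij)^gamma Y_ij log(P_ij)``.

    ``I`` is the number of voxels (all leading axes).  Reduces to
    alpha-scaled mean cross-entropy at ``gamma = 0``.
    """
    _check_pair(p, y)

    def _fn(pt: Tensor, yt: Tensor) -> Tensor:
        n_voxels = int(np.prod(pt.shape[:-1])) or 1
        logp = pt.clip(_LOG_EPS, 1.0).log()
        term = (1.0 - pt) ** gamma * yt * logp
        return term.sum() * (-alpha / n_voxels)

    return _eval(_fn, p, y)


def dice_loss(p, y):
    """``1 - 2 sum(PY) / (sum(P^2) + sum(Y^2))`` over voxels and classes.

    A smoothing constant guards the empty-target corner case; with binary
    inputs the value lies in [0, 1].
    """
    _check_pair(p, y)

    def _fn(pt: Tensor, yt: Tensor) -> Tensor:
        inter = (pt * yt).sum()
        denom = (pt * pt).sum() + (yt * yt).sum()
        return 1.0 - (2.0 * inter + _DICE_SMOOTH) / (denom + _DICE_SMOOTH)

    return _eval(_fn, p, y)


def hybrid_loss(p, y, weights: LossWeights = LossWeights()):
    """``lam_dice * dice + lam_focal * focal`` (defaults: plain sum)."""
    _check_pair(p, y)

    def _fn(pt: Tensor, yt: Tensor) -> Tensor:
        total = None
        if weights.lam_dice:
            total = weights.lam_dice * dice_loss(pt, yt)
        if weights.lam_focal:
            fl = weights.lam_focal * focal_loss(pt, yt, weights.alpha,
                                                weights.gamma)
            total = fl if total is None else total + fl
        return total

    return _eval(_fn, p, y)
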