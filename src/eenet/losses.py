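"""Hybrid segmentation loss: weighted cross-entropy plus edge-aware loss.

    L_hybrid = alpha * L_CE + beta * L_edge        (alpha = beta = 0.5 default)

L_CE is the pixel-averaged cross-entropy between per-pixel class
probabilities P and one-hot ground truth Y, normalised by H*W (the class sum
is inside the pixel average).  L_edge compares Sobel gradient-magnitude edge
maps of the foreground planes of P and Y by their mean absolute difference.

The edge extractor used *inside the loss* is the fixed (non-learnable)
Sobel operator, not the learnable Canny kernel: the loss must be a fixed
yardstick, since a learnable target could collapse to zero edges.

Every function accepts either plain ndarrays (returning floats/arrays) or
autodiff tensors (returning tensors, so the loss can be backpropagated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edge_kernel import SOBEL_X, SOBEL_Y
from .tensor import Tensor, as_tensor, conv2d_valid, pad_reflect

__all__ = [
    "LossWeights",
    "EdgeMapPair",
    "cross_entropy_loss",
    "edge_map",
    "edge_aware_loss",
    "hybrid_loss",
    "PROB_EPS",
]

PROB_EPS = 1e-7  # probability clamp before the log
_EDGE_EPS = 1e-12  # keeps the magnitude gradient finite in the autodiff path


@dataclass
class LossWeights:
    """Mixing weights of the cross-entropy and edge terms."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha + self.beta <= 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class EdgeMapPair:
    """Ground-truth and predicted edge-magnitude maps of equal extent."""

    e_gt: np.ndarray
    e_pred: np.ndarray

    def __post_init__(self):
        self.e_gt = np.asarray(self.e_gt, dtype=float)
        self.e_pred = np.asarray(self.e_pred, dtype=float)
        if self.e_gt.shape != self.e_pred.shape:
            raise ValueError("edge maps must share one shape")
        if not (np.all(np.isfinite(self.e_gt)) and np.all(np.isfinite(self.e_pred))):
            raise ValueError("edge maps must be finite")


def _validate_one_hot(y: np.ndarray, class_axis: int) -> None:
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("ground truth must be one-hot (entries 0/1)")
    sums = y.sum(axis=class_axis)
    if not np.allclose(sums, 1.0):
        raise ValueError("ground truth must be one-hot (class sums must be 1)")


def cross_entropy_loss(p, y):
    """Pixel-averaged cross-entropy  -(1/HW) sum_{i,j} sum_c Y log P.

    ``p`` and ``y`` are (C, H, W) maps or (N, C, H, W) batches; batches are
    additionally averaged over N.  Probabilities are clamped at 1e-7 before
    the log.
    """
    is_tensor = isinstance(p, Tensor)
    pt = as_tensor(p)
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=float)
    if pt.ndim not in (3, 4):
        raise ValueError("expected (C, H, W) or (N, C, H, W) maps")
    class_axis = 0 if pt.ndim == 3 else 1
    _validate_one_hot(y_arr, class_axis)
    if y_arr.shape != pt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    logp = pt.clamp(PROB_EPS, 1.0).log()
    per_pixel = -(Tensor(y_arr) * logp).sum(axis=class_axis)
    loss = per_pixel.mean()
    return loss if is_tensor else float(loss.data)


def _sobel_magnitude(m: Tensor, eps: float) -> Tensor:
    """Shape-preserving Sobel gradient magnitude of (..., H, W) maps."""
    shape = m.shape
    lead = int(np.prod(shape[:-2])) if len(shape) > 2 else 1
    flat = m.reshape(lead, 1, shape[-2], shape[-1])
    padded = pad_reflect(flat, 1, 1)
    gx = conv2d_valid(padded, Tensor(SOBEL_X[None, None]))
    gy = conv2d_valid(padded, Tensor(SOBEL_Y[None, None]))
    if eps > 0:
        mag = (gx * gx + gy * gy + eps).sqrt()
    else:
        mag = (gx * gx + gy * gy).sqrt()
    return mag.reshape(shape)


def edge_map(m) -> np.ndarray:
    """Fixed Sobel gradient magnitude of an H x W map (mirror padded).

    This is the Edge(.) operator of the loss, applied to the foreground
    plane of a probability or ground-truth map.
    """
    arr = np.asarray(m, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected an (H, W) map, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("map must be finite")
    return _sobel_magnitude(Tensor(arr), eps=0.0).data


def edge_aware_loss(pair: EdgeMapPair) -> float:
    """Mean absolute difference between predicted and ground-truth edge maps."""
    return float(np.mean(np.abs(pair.e_pred - pair.e_gt)))


def hybrid_loss(p, y, w: LossWeights = LossWeights()):
    """alpha * L_CE + beta * L_edge on (N, C, H, W) or (C, H, W) maps.

    The edge term compares Sobel magnitudes of the foreground planes
    (class index 1).  Tensor input keeps the result differentiable.
    """
    is_tensor = isinstance(p, Tensor)
    pt = as_tensor(p)
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=float)
    ce = cross_entropy_loss(pt, y_arr)
    if pt.ndim == 3:
        fg_pred, fg_gt = pt[1], Tensor(y_arr[1])
    else:
        fg_pred, fg_gt = pt[:, 1], Tensor(y_arr[:, 1])
    e_pred = _sobel_magnitude(fg_pred, eps=_EDGE_EPS)
    e_gt = _sobel_magnitude(fg_gt, eps=_EDGE_EPS)
    ledge = (e_pred - e_gt).abs().mean()
    total = w.alpha * ce + w.beta * ledge
    return total if is_tensor else float(total.data)
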