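"""Learnable Canny-style edge convolution (ConvLCK).

Classical Canny edge detection (Gaussian smoothing, Sobel gradients,
non-maximum suppression, hysteresis) is not differentiable, so it cannot sit
inside a trained network.  ConvLCK keeps the differentiable first half and
makes it learnable: a 5x5 smoothing kernel initialised to a normalised
Gaussian, a pair of 3x3 gradient kernels initialised to the Sobel x/y
operators, and a per-pixel gradient magnitude sqrt(Gx^2 + Gy^2 + eps).  The
non-maximum suppression and double-threshold stages are deliberately
omitted.

The operator is applied depthwise: every channel of a C x H x W feature map
is smoothed and differentiated with the *same* learnable kernel set, so the
output has the same shape as the input and channel permutation commutes with
the operator.  Mirror padding keeps the spatial extent unchanged and avoids
the artificial border response that zero padding would create.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Module, Parameter
from .tensor import Tensor, as_tensor, conv2d_valid, pad_reflect

__all__ = [
    "EdgeKernelParams",
    "ConvLCK",
    "init_edge_kernel",
    "conv_lck",
    "SOBEL_X",
    "SOBEL_Y",
    "gaussian_kernel",
]

SMOOTH_SIZE = 5
DEFAULT_EPS_MAG = 1e-8

SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T.copy()


def gaussian_kernel(sigma: float, size: int = SMOOTH_SIZE) -> np.ndarray:
    """Discretised isotropic Gaussian on a size x size grid, normalised to sum 1."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    half = size // 2
    ii, jj = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij")
    k = np.exp(-(ii ** 2 + jj ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


@dataclass
class EdgeKernelParams:
    """Learnable-edge-kernel weights as plain arrays (the functional API)."""

    smooth_weights: np.ndarray
    grad_x_weights: np.ndarray
    grad_y_weights: np.ndarray
    eps_mag: float = DEFAULT_EPS_MAG

    def __post_init__(self):
        self.smooth_weights = np.asarray(self.smooth_weights, dtype=float)
        self.grad_x_weights = np.asarray(self.grad_x_weights, dtype=float)
        self.grad_y_weights = np.asarray(self.grad_y_weights, dtype=float)
        if self.eps_mag <= 0:
            raise ValueError("eps_mag must be positive")


def init_edge_kernel(sigma: float, seed: int = 0) -> EdgeKernelParams:
    """Gaussian/Sobel initialisation of the learnable edge kernel.

    The initial state is fully determined by ``sigma``; ``seed`` is accepted
    for interface symmetry with the other constructors and reserved for
    future stochastic initialisers.
    """
    del seed  # deterministic initialisation
    return EdgeKernelParams(
        smooth_weights=gaussian_kernel(sigma),
        grad_x_weights=SOBEL_X.copy(),
        grad_y_weights=SOBEL_Y.copy(),
    )


def _edge_response(x: Tensor, smooth: Tensor, gx: Tensor, gy: Tensor, eps_mag: float) -> Tensor:
    """Depthwise smooth -> gradient pair -> magnitude, shape preserving."""
    n, c, h, w = x.shape
    flat = x.reshape(n * c, 1, h, w)
    sm = conv2d_valid(pad_reflect(flat, SMOOTH_SIZE // 2, SMOOTH_SIZE // 2),
                      smooth.reshape(1, 1, SMOOTH_SIZE, SMOOTH_SIZE))
    smp = pad_reflect(sm, 1, 1)
    rx = conv2d_valid(smp, gx.reshape(1, 1, 3, 3))
    ry = conv2d_valid(smp, gy.reshape(1, 1, 3, 3))
    mag = (rx * rx + ry * ry + eps_mag).sqrt()
    return mag.reshape(n, c, h, w)


class ConvLCK(Module):
    """Learnable Canny kernel convolution as a trainable module.

    One instance holds a single shared smoothing/gradient kernel set that is
    applied depthwise to every channel of its input, whatever the channel
    count.  This is what lets a single instance serve as the shared edge
    extractor across all skip levels of the cross-scale module.
    """

    def __init__(self, sigma: float = 1.0, eps_mag: float = DEFAULT_EPS_MAG, seed: int = 0):
        super().__init__()
        init = init_edge_kernel(sigma, seed)
        self.smooth_weights = Parameter(init.smooth_weights)
        self.grad_x_weights = Parameter(init.grad_x_weights)
        self.grad_y_weights = Parameter(init.grad_y_weights)
        self.eps_mag = eps_mag

    def forward(self, x: Tensor) -> Tensor:
        return _edge_response(
            x, self.smooth_weights, self.grad_x_weights, self.grad_y_weights, self.eps_mag
        )

    def export_params(self) -> EdgeKernelParams:
        return EdgeKernelParams(
            self.smooth_weights.data.copy(),
            self.grad_x_weights.data.copy(),
            self.grad_y_weights.data.copy(),
            self.eps_mag,
        )


def conv_lck(params, f):
    """Edge-magnitude response of a feature map.

    Parameters
    ----------
    params : EdgeKernelParams or ConvLCK
        Kernel weights.
    f : ndarray of shape (C, H, W) or (N, C, H, W), or Tensor
        Input feature map(s); each channel is processed independently.

    Returns
    -------
    Same kind and shape as ``f``: an ndarray input yields an ndarray, a
    Tensor input stays in the autodiff graph.
    """
    if isinstance(params, ConvLCK):
        smooth, gx, gy = params.smooth_weights, params.grad_x_weights, params.grad_y_weights
        eps = params.eps_mag
    else:
        smooth = as_tensor(params.smooth_weights)
        gx = as_tensor(params.grad_x_weights)
        gy = as_tensor(params.grad_y_weights)
        eps = params.eps_mag
    if isinstance(f, Tensor):
        return _edge_response(f, smooth, gx, gy, eps)
    arr = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature map must be finite")
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    out = _edge_response(Tensor(arr), smooth, gx, gy, eps).data
    return out[0] if squeeze else out
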