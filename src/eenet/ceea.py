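"""Covariance edge-enhanced attention (CEEA).

The module compares a feature map F_in with its edge-enhanced counterpart
F_e = ConvLCK(F_in) through two covariance-derived attention maps:

* channel attention  A_c = softmax((1/HW) F_in'' (F_e'')^T), a C x C
  row-stochastic matrix built from the channel covariance of the two
  centred, flattened maps;
* position attention A_p = softmax((1/HW) (F_e'')^T F_in''), an HW x HW
  row-stochastic matrix over spatial positions.

Both use the biased 1/HW covariance normalisation.  The refined output is a
dual-branch residual

    F_out = F_in + gamma_c * unflatten(A_c F_in'') + gamma_p * unflatten(F_in'' A_p^T)

with the scalar gates gamma_c, gamma_p learnable and initialised to zero, so
the module is the exact identity at initialisation and the attention
branches are blended in during training.

Because A_p is quadratic in the number of pixels, position attention is
computed on an average-pooled grid whenever HW exceeds ``spatial_cap``
(default 1024 positions, i.e. at most 32x32 tokens); the refined spatial
branch is bilinearly upsampled back to full resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .edge_kernel import ConvLCK
from .nn import Module, Parameter, adaptive_avg_pool, resize_bilinear
from .tensor import Tensor, softmax

__all__ = [
    "CenteredFlatMap",
    "CovMatrix",
    "ChannelAttn",
    "SpatialAttn",
    "SpatialCapExceeded",
    "DEFAULT_SPATIAL_CAP",
    "center_and_flatten",
    "channel_covariance",
    "channel_attention",
    "spatial_covariance_attention",
    "CEEA",
    "ceea_forward",
]

DEFAULT_SPATIAL_CAP = 1024


class SpatialCapExceeded(RuntimeError):
    """Raised when a full HW x HW attention map would be too large."""


@dataclass
class CenteredFlatMap:
    """A channel-centred, row-major-flattened feature map (C x HW)."""

    values: np.ndarray
    source_dims: Tuple[int, int, int]


@dataclass
class CovMatrix:
    """C x C channel covariance (units: input units squared)."""

    values: np.ndarray


@dataclass
class ChannelAttn:
    """C x C row-stochastic channel attention weights."""

    values: np.ndarray


@dataclass
class SpatialAttn:
    """HW x HW row-stochastic position attention weights."""

    values: np.ndarray
    grid_dims: Tuple[int, int]


def center_and_flatten(f: np.ndarray) -> CenteredFlatMap:
    """Subtract each channel's mean and flatten the channel planes row-major."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError(f"expected a (C, H, W) feature map, got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError("feature map must be finite")
    c, h, w = f.shape
    flat = f.reshape(c, h * w)
    return CenteredFlatMap(flat - flat.mean(axis=1, keepdims=True), (c, h, w))


def channel_covariance(a: CenteredFlatMap, b: CenteredFlatMap) -> CovMatrix:
    """Biased channel covariance (1/HW) a b^T between two centred maps."""
    if a.source_dims != b.source_dims:
        raise ValueError(f"source dims differ: {a.source_dims} vs {b.source_dims}")
    hw = a.values.shape[1]
    return CovMatrix(a.values @ b.values.T / hw)


def channel_attention(cov: CovMatrix) -> ChannelAttn:
    """Row-wise softmax of the channel covariance."""
    return ChannelAttn(softmax(Tensor(cov.values), axis=-1).data)


def spatial_covariance_attention(
    e: CenteredFlatMap,
    f: CenteredFlatMap,
    spatial_cap: int = DEFAULT_SPATIAL_CAP,
) -> SpatialAttn:
    """Position attention softmax((1/HW) e^T f) between two centred maps.

    Raises :class:`SpatialCapExceeded` when HW exceeds ``spatial_cap``; the
    CEEA module avoids this by pooling the spatial grid first.
    """
    if e.source_dims != f.source_dims:
        raise ValueError(f"source dims differ: {e.source_dims} vs {f.source_dims}")
    _, h, w = e.source_dims
    hw = h * w
    if hw > spatial_cap:
        raise SpatialCapExceeded(
            f"HW = {hw} exceeds the spatial attention cap ({spatial_cap}); "
            "pool the maps to a coarser grid first (the CEEA module does this "
            "automatically) or raise spatial_cap."
        )
    cov = e.values.T @ f.values / hw
    return SpatialAttn(softmax(Tensor(cov), axis=-1).data, (h, w))


def _center_flat(x: Tensor) -> Tensor:
    """(N, C, H, W) -> channel-centred (N, C, HW)."""
    n, c, h, w = x.shape
    flat = x.reshape(n, c, h * w)
    return flat - flat.mean(axis=2, keepdims=True)


def _pool_dims(h: int, w: int, cap: int) -> Tuple[int, int]:
    """Halve the grid until it holds at most `cap` positions."""
    while h * w > cap:
        h = max(1, -(-h // 2))
        w = max(1, -(-w // 2))
    return h, w


class CEEA(Module):
    """Covariance edge-enhanced attention block.

    Each instance owns its own learnable Canny kernel and two zero-initialised
    residual gates, so a freshly built block is an exact identity map.
    """

    def __init__(
        self,
        sigma: float = 1.0,
        spatial_cap: int = DEFAULT_SPATIAL_CAP,
        seed: int = 0,
    ):
        super().__init__()
        self.lck = ConvLCK(sigma=sigma, seed=seed)
        self.gamma_c = Parameter(0.0)
        self.gamma_p = Parameter(0.0)
        self.spatial_cap = spatial_cap

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        hw = h * w
        fe = self.lck(x)

        xf = _center_flat(x)
        ef = _center_flat(fe)

        # channel branch: A_c (C x C) applied to the centred input rows
        cov_c = (xf @ ef.transpose(0, 2, 1)) * (1.0 / hw)
        a_c = softmax(cov_c, axis=-1)
        branch_c = (a_c @ xf).reshape(n, c, h, w)

        # position branch, on a pooled grid when HW exceeds the cap
        hp, wp = _pool_dims(h, w, self.spatial_cap)
        if (hp, wp) != (h, w):
            xp = adaptive_avg_pool(x, hp, wp)
            ep = adaptive_avg_pool(fe, hp, wp)
        else:
            xp, ep = x, fe
        xpf = _center_flat(xp)
        epf = _center_flat(ep)
        # fold the 1/HW normalisation into the small factor before the big matmul
        cov_p = (epf * (1.0 / (hp * wp))).transpose(0, 2, 1) @ xpf
        a_p = softmax(cov_p, axis=-1)
        branch_p = (xpf @ a_p.transpose(0, 2, 1)).reshape(n, c, hp, wp)
        if (hp, wp) != (h, w):
            branch_p = resize_bilinear(branch_p, h, w)

        return x + self.gamma_c * branch_c + self.gamma_p * branch_p


def ceea_forward(params: CEEA, f: np.ndarray) -> np.ndarray:
    """Apply a CEEA block to a single (C, H, W) feature map (ndarray API)."""
    arr = np.asarray(f, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected a (C, H, W) feature map, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature map must be finite")
    return params(Tensor(arr[None])).data[0]
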