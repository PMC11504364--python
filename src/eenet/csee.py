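"""Cross-scale edge enhancement (CSEE) for encoder-decoder skip fusion.

At each skip connection the encoder features F_enc and the (aligned) decoder
features F_dec are both passed through a *shared* learnable Canny kernel,
centred and flattened, and compared through a channel covariance

    A_csee = softmax((1/HW) F''_e,enc (F''_e,dec)^T)

which reweights the encoder's edge channels by how strongly they co-vary
with the decoder's.  The fused output is

    F_csee = F_dec + F_enc + gamma_s * unflatten(A_csee F''_e,enc)

with the scalar gate gamma_s learnable and zero-initialised, so at
initialisation the skip reduces exactly to the plain additive U-Net skip.
Unlike the encoder-side attention block, no position branch is used here:
the cross-scale comparison is channel-wise only.

Feature maps arriving from different depths of the network first go through
:func:`align_skip` (bilinear resize plus 1x1 channel projection) so the two
streams share a common C x H x W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ceea import _center_flat
from .edge_kernel import ConvLCK
from .nn import Conv2d, Module, Parameter, resize_bilinear
from .tensor import Tensor, softmax

__all__ = ["SkipPair", "CSEE", "csee_forward", "SkipAlign", "align_skip"]


@dataclass
class SkipPair:
    """Aligned encoder/decoder feature maps sharing one C x H x W."""

    enc: np.ndarray
    dec: np.ndarray

    def __post_init__(self):
        self.enc = np.asarray(self.enc, dtype=float)
        self.dec = np.asarray(self.dec, dtype=float)
        if self.enc.shape != self.dec.shape:
            raise ValueError(
                f"encoder/decoder shapes differ: {self.enc.shape} vs {self.dec.shape}"
            )
        if self.enc.ndim != 3:
            raise ValueError("SkipPair expects (C, H, W) maps")


class CSEE(Module):
    """Cross-scale edge-enhancement skip fusion.

    ``lck`` is a ConvLCK instance that is typically *shared* between every
    CSEE block of a network (and between the encoder and decoder streams
    within a block); sharing is by object identity, and the parameter
    traversal deduplicates it.
    """

    def __init__(self, lck: ConvLCK):
        super().__init__()
        self.lck = lck
        self.gamma_s = Parameter(0.0)

    def forward(self, enc: Tensor, dec: Tensor) -> Tensor:
        if enc.shape != dec.shape:
            raise ValueError(f"encoder/decoder shapes differ: {enc.shape} vs {dec.shape}")
        n, c, h, w = enc.shape
        hw = h * w
        fe_enc = self.lck(enc)
        fe_dec = self.lck(dec)
        ef = _center_flat(fe_enc)
        df = _center_flat(fe_dec)
        cov = (ef @ df.transpose(0, 2, 1)) * (1.0 / hw)
        attn = softmax(cov, axis=-1)
        refined = (attn @ ef).reshape(n, c, h, w)
        return dec + enc + self.gamma_s * refined


def csee_forward(params: CSEE, pair: SkipPair) -> np.ndarray:
    """Apply a CSEE block to one aligned (C, H, W) skip pair (ndarray API)."""
    enc = Tensor(pair.enc[None])
    dec = Tensor(pair.dec[None])
    return params(enc, dec).data[0]


class SkipAlign(Module):
    """Bilinear resize plus 1x1 channel projection of the decoder stream.

    When the channel counts already match, the projection initialises to the
    identity so alignment starts as a no-op.
    """

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        super().__init__()
        if in_channels == out_channels:
            self.proj = Conv2d(in_channels, out_channels, 1, identity_init=True)
        else:
            self.proj = Conv2d(in_channels, out_channels, 1, rng=rng)
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, dec: Tensor, target_hw) -> Tensor:
        dec = resize_bilinear(dec, target_hw[0], target_hw[1])
        return self.proj(dec)


def align_skip(enc: np.ndarray, dec: np.ndarray, seed: int = 0) -> SkipPair:
    """Align a decoder map to an encoder map's C x H x W (ndarray API).

    The decoder map is bilinearly resized to the encoder's spatial extent and
    passed through a deterministic 1x1 channel projection (identity when the
    channel counts already match, seeded He initialisation otherwise).
    """
    enc = np.asarray(enc, dtype=float)
    dec = np.asarray(dec, dtype=float)
    if enc.ndim != 3 or dec.ndim != 3:
        raise ValueError("align_skip expects (C, H, W) maps")
    align = SkipAlign(dec.shape[0], enc.shape[0], rng=np.random.default_rng(seed))
    aligned = align(Tensor(dec[None]), enc.shape[1:]).data[0]
    return SkipPair(enc, aligned)
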