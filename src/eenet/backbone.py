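"""The edge-enhanced encoder-decoder network (EENet) and its ablations.

The assembly is U-Net shaped: each encoder stage is two convolution blocks
(CB = 3x3 mirror-padded convolution + batch norm + ReLU) followed by an
attention module and 2x max pooling (except after the deepest stage); the
decoder mirrors it with 2x bilinear upsampling, a skip fusion (cross-scale
edge enhancement, or plain addition), and two more CBs.  A 1x1 convolution
and a pixel-wise softmax produce per-class probability maps.

The attention slot is a switchboard for the ablation variants:

* ``ceea`` - covariance edge-enhanced attention (the full model);
* ``conv`` - one extra CB in place of the attention block;
* ``self`` - single-head scaled dot-product self-attention over pooled
  spatial tokens, with a residual connection;
* ``none`` - no attention module (the plain U-Net-style counterpart).

Setting ``use_csee=False`` replaces every cross-scale skip fusion with plain
addition and removes all of its parameters.

Parameter initialisation is derived per module path from the configuration
seed, so two configurations that share a sub-module initialise it
identically regardless of which optional branches are present.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from typing import List, Optional, Tuple

import numpy as np

from .ceea import CEEA, DEFAULT_SPATIAL_CAP, _pool_dims
from .csee import CSEE, SkipAlign
from .edge_kernel import ConvLCK
from .nn import (
    BatchNorm2d,
    Conv2d,
    Module,
    ModuleList,
    adaptive_avg_pool,
    resize_bilinear,
)
from .tensor import Tensor, maxpool2x2, reflect_indices, softmax

__all__ = [
    "NetworkConfig",
    "CBBlock",
    "cb_block",
    "SelfAttention2d",
    "EENet",
    "build_eenet",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]

ATTENTION_VARIANTS = ("ceea", "conv", "self", "none")
CHECKPOINT_VERSION = 1


@dataclass
class NetworkConfig:
    """Architecture hyperparameters and ablation switches."""

    stage_channels: Tuple[int, ...] = (32, 64, 128, 256, 512)
    num_classes: int = 2
    in_channels: int = 3
    attention_variant: str = "ceea"
    use_csee: bool = True
    seed: int = 0
    spatial_cap: int = DEFAULT_SPATIAL_CAP
    lck_sigma: float = 1.0

    def validate(self) -> None:
        if len(self.stage_channels) < 2:
            raise ValueError("need at least two encoder stages")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.attention_variant not in ATTENTION_VARIANTS:
            raise ValueError(
                f"unknown attention variant {self.attention_variant!r}; "
                f"choose one of {ATTENTION_VARIANTS}"
            )


def _path_rng(seed: int, path: str) -> np.random.Generator:
    """Deterministic generator for one module path: stable across variants."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(path.encode()) & 0x7FFFFFFF])


class CBBlock(Module):
    """Convolution block: 3x3 mirror-padded conv, batch norm, ReLU."""

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, rng=rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


def cb_block(params: CBBlock, f: np.ndarray) -> np.ndarray:
    """Apply a CB block to a single (C, H, W) feature map (ndarray API)."""
    arr = np.asarray(f, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected a (C, H, W) feature map, got shape {arr.shape}")
    return params(Tensor(arr[None])).data[0]


class SelfAttention2d(Module):
    """Single-head scaled dot-product self-attention over pooled positions.

    Q, K, V and the output projection are 1x1 convolutions; attention is
    computed over an average-pooled token grid of at most ``spatial_cap``
    positions, upsampled back, and added residually.
    """

    def __init__(self, channels: int, spatial_cap: int = DEFAULT_SPATIAL_CAP, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.q = Conv2d(channels, channels, 1, rng=rng)
        self.k = Conv2d(channels, channels, 1, rng=rng)
        self.v = Conv2d(channels, channels, 1, rng=rng)
        self.out = Conv2d(channels, channels, 1, rng=rng)
        self.spatial_cap = spatial_cap
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        hp, wp = _pool_dims(h, w, self.spatial_cap)
        xt = adaptive_avg_pool(x, hp, wp) if (hp, wp) != (h, w) else x
        q = self.q(xt).reshape(n, c, hp * wp)
        k = self.k(xt).reshape(n, c, hp * wp)
        v = self.v(xt).reshape(n, c, hp * wp)
        attn = softmax((q * (1.0 / np.sqrt(c))).transpose(0, 2, 1) @ k, axis=-1)
        y = (v @ attn.transpose(0, 2, 1)).reshape(n, c, hp, wp)
        y = self.out(y)
        if (hp, wp) != (h, w):
            y = resize_bilinear(y, h, w)
        return x + y


class _EncStage(Module):
    def __init__(self, cb1, cb2, attn):
        super().__init__()
        self.cb1 = cb1
        self.cb2 = cb2
        if attn is not None:
            self.attn = attn
        else:
            self.attn = None


class _DecStage(Module):
    def __init__(self, align, csee, cb1, cb2):
        super().__init__()
        self.align = align
        if csee is not None:
            self.csee = csee
        else:
            self.csee = None
        self.cb1 = cb1
        self.cb2 = cb2


class EENet(Module):
    """Edge-enhanced encoder-decoder segmentation network."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        config.validate()
        self.config = config
        ch = tuple(config.stage_channels)
        n_stages = len(ch)
        seed = config.seed

        if config.use_csee:
            # one learnable Canny kernel shared by every skip-fusion block
            self.lck_shared = ConvLCK(sigma=config.lck_sigma)
        else:
            self.lck_shared = None

        enc = []
        prev = config.in_channels
        for i, c in enumerate(ch):
            cb1 = CBBlock(prev, c, rng=_path_rng(seed, f"enc{i}.cb1"))
            cb2 = CBBlock(c, c, rng=_path_rng(seed, f"enc{i}.cb2"))
            attn = self._make_attention(c, seed, f"enc{i}.attn")
            enc.append(_EncStage(cb1, cb2, attn))
            prev = c
        self.encoder = ModuleList(enc)

        dec = []
        for i in range(n_stages - 2, -1, -1):
            align = SkipAlign(ch[i + 1], ch[i], rng=_path_rng(seed, f"dec{i}.align"))
            csee = CSEE(self.lck_shared) if config.use_csee else None
            cb1 = CBBlock(ch[i], ch[i], rng=_path_rng(seed, f"dec{i}.cb1"))
            cb2 = CBBlock(ch[i], ch[i], rng=_path_rng(seed, f"dec{i}.cb2"))
            dec.append(_DecStage(align, csee, cb1, cb2))
        self.decoder = ModuleList(dec)

        self.head = Conv2d(ch[0], config.num_classes, 1, rng=_path_rng(seed, "head"))

    def _make_attention(self, channels: int, seed: int, path: str) -> Optional[Module]:
        variant = self.config.attention_variant
        if variant == "ceea":
            return CEEA(sigma=self.config.lck_sigma, spatial_cap=self.config.spatial_cap)
        if variant == "conv":
            return CBBlock(channels, channels, rng=_path_rng(seed, path))
        if variant == "self":
            return SelfAttention2d(
                channels, spatial_cap=self.config.spatial_cap, rng=_path_rng(seed, path)
            )
        return None  # "none": plain U-Net counterpart

    @property
    def downsample_factor(self) -> int:
        return 2 ** (len(self.config.stage_channels) - 1)

    def forward(self, x: Tensor) -> Tensor:
        """Probability maps (N, num_classes, H, W); rows of the class axis sum to 1."""
        n_stages = len(self.config.stage_channels)
        feats: List[Tensor] = []
        h = x
        for i, stage in enumerate(self.encoder):
            h = stage.cb2(stage.cb1(h))
            if stage.attn is not None:
                h = stage.attn(h)
            feats.append(h)
            if i < n_stages - 1:
                h = maxpool2x2(h)
        d = feats[-1]
        for stage, i in zip(self.decoder, range(n_stages - 2, -1, -1)):
            skip = feats[i]
            d = stage.align(d, (skip.shape[2], skip.shape[3]))
            if stage.csee is not None:
                d = stage.csee(skip, d)
            else:
                d = skip + d
            d = stage.cb2(stage.cb1(d))
        logits = self.head(d)
        return softmax(logits, axis=1)


def build_eenet(config: NetworkConfig) -> EENet:
    """Construct an EENet from a configuration (validating it first)."""
    config.validate()
    return EENet(config)


def predict_mask(net: EENet, image: np.ndarray) -> np.ndarray:
    """Binary segmentation of one (3, H, W) image in [0, 1].

    Inputs whose extent is not a multiple of the network's total downsample
    factor are mirror-padded, and the prediction is cropped back, so the
    output mask always matches the input spatially.  Inference is
    deterministic (eval mode, running batch-norm statistics).
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected a (C, H, W) image, got shape {arr.shape}")
    _, h, w = arr.shape
    m = net.downsample_factor
    ph = (-h) % m
    pw = (-w) % m
    if ph or pw:
        # trailing-side mirror pad (robust to tiny inputs), cropped back below
        hh = reflect_indices(h, ph)[ph:] if ph else np.arange(h)
        ww = reflect_indices(w, pw)[pw:] if pw else np.arange(w)
        arr = arr[:, hh][:, :, ww]
    x = Tensor(arr[None])
    was_training = net.training
    net.eval()
    probs = net(x).data[0]
    if was_training:
        net.train()
    probs = probs[:, :h, :w]
    return np.argmax(probs, axis=0).astype(np.uint8)


def save_checkpoint(path, net: EENet) -> None:
    """Serialise weights plus the embedded NetworkConfig (self-describing)."""
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(net.config)}
    state = net.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> EENet:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as zf:
        meta = json.loads(bytes(zf["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        cfg_dict = meta["config"]
        cfg_dict["stage_channels"] = tuple(cfg_dict["stage_channels"])
        config = NetworkConfig(**cfg_dict)
        state = {k: zf[k] for k in zf.files if k != "__meta__"}
    net = build_eenet(config)
    net.load_state_dict(state)
    return net
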