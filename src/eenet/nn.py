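"""Neural-network building blocks on top of the autodiff tensor engine.

Provides the usual Module/Parameter containers, 2-D convolution with mirror
padding, batch normalisation, bilinear resizing and adaptive average pooling
(both expressed as fixed interpolation matrices so their gradients come for
free from matmul), and plain SGD with momentum.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .tensor import Tensor, conv2d_valid, pad_reflect

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Conv2d",
    "BatchNorm2d",
    "SGD",
    "resize_bilinear",
    "adaptive_avg_pool",
    "bilinear_matrix",
    "avg_pool_matrix",
]


class Parameter(Tensor):
    """A tensor that is updated by the optimiser."""

    def __init__(self, data):
        super().__init__(np.array(data, dtype=np.float64), requires_grad=True)


class Module:
    """Base class with automatic parameter/submodule registration.

    Submodules may be *shared* (the same object referenced from several
    places, e.g. one learnable Canny kernel used by every cross-scale skip
    module); traversal deduplicates by object identity so shared parameters
    are counted and updated exactly once.
    """

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        """Update a registered buffer in place of the registry."""
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # ---- traversal -------------------------------------------------------
    def named_parameters(self, prefix: str = "", _seen=None) -> Iterator[Tuple[str, Parameter]]:
        if _seen is None:
            _seen = set()
        for name, p in self._params.items():
            if id(p) not in _seen:
                _seen.add(id(p))
                yield (prefix + name, p)
        for name, m in self._modules.items():
            if id(m) in _seen:
                continue
            _seen.add(id(m))
            yield from m.named_parameters(prefix + name + ".", _seen)

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "", _seen=None) -> Iterator[Tuple[str, "Module", str]]:
        if _seen is None:
            _seen = set()
        for name in self._buffers:
            yield (prefix + name, self, name)
        for name, m in self._modules.items():
            if id(m) in _seen:
                continue
            _seen.add(id(m))
            yield from m.named_buffers(prefix + name + ".", _seen)

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # ---- (de)serialisation ----------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, owner, attr in self.named_buffers():
            state["buffer:" + name] = np.array(getattr(owner, attr), copy=True)
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: (owner, attr) for name, owner, attr in self.named_buffers()}
        for key, value in state.items():
            if key.startswith("buffer:"):
                owner, attr = buffers[key[len("buffer:"):]]
                owner._set_buffer(attr, np.array(value, copy=True))
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data = np.array(value, dtype=np.float64, copy=True)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: List[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        setattr(self, str(len(self._list)), module)
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    """2-D convolution (cross-correlation) with 'same' mirror padding.

    Weights use He initialisation from the supplied generator; a square
    identity-initialised 1x1 projection is available for no-op alignment.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: Optional[np.random.Generator] = None,
        bias: bool = True,
        identity_init: bool = False,
    ):
        super().__init__()
        k = kernel_size
        if identity_init:
            if in_channels != out_channels:
                raise ValueError("identity init requires matching channel counts")
            w = np.zeros((out_channels, in_channels, k, k))
            w[np.arange(out_channels), np.arange(in_channels), k // 2, k // 2] = 1.0
        else:
            if rng is None:
                rng = np.random.default_rng(0)
            std = np.sqrt(2.0 / (in_channels * k * k))
            w = rng.normal(0.0, std, size=(out_channels, in_channels, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.kernel_size = k

    def forward(self, x: Tensor) -> Tensor:
        pad = self.kernel_size // 2
        if pad:
            x = pad_reflect(x, pad, pad)
        return conv2d_valid(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel.

    Training mode normalises with batch statistics and updates running
    averages (momentum 0.1, unbiased variance); eval mode uses the running
    averages.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.channels = channels
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        c = self.channels
        gamma = self.gamma.reshape(1, c, 1, 1)
        beta = self.beta.reshape(1, c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.size // c
            unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
            m = self.momentum
            self._set_buffer("running_mean", (1 - m) * self.running_mean + m * mu.data.reshape(c))
            self._set_buffer("running_var", (1 - m) * self.running_var + m * unbiased)
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var.reshape(1, c, 1, 1) + self.eps)
            xhat = (x - mu) / sd
        return gamma * xhat + beta


def bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) bilinear interpolation matrix (half-pixel centres)."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    for row, (a0, a1, w) in enumerate(zip(i0, i1, w1)):
        a[row, a0] += 1.0 - w
        a[row, a1] += w
    return a


def avg_pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) adaptive average-pooling matrix with equal bin weights."""
    a = np.zeros((n_out, n_in))
    for row in range(n_out):
        lo = (row * n_in) // n_out
        hi = -(-((row + 1) * n_in) // n_out)  # ceil division
        a[row, lo:hi] = 1.0 / (hi - lo)
    return a


def _apply_sep_matrices(x: Tensor, ah: np.ndarray, aw: np.ndarray) -> Tensor:
    """y[n,c] = ah @ x[n,c] @ aw.T for a (N, C, H, W) tensor."""
    y = x @ Tensor(aw.T)  # (N, C, H, Wo)
    y = y.transpose(0, 1, 3, 2) @ Tensor(ah.T)  # (N, C, Wo, Ho)
    return y.transpose(0, 1, 3, 2)


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinearly resize the spatial dims of a (N, C, H, W) tensor."""
    _, _, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    return _apply_sep_matrices(x, bilinear_matrix(h, out_h), bilinear_matrix(w, out_w))


def adaptive_avg_pool(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Adaptive average pooling of a (N, C, H, W) tensor to (out_h, out_w)."""
    _, _, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    return _apply_sep_matrices(x, avg_pool_matrix(h, out_h), avg_pool_matrix(w, out_w))


class SGD:
    """Stochastic gradient descent with classical momentum.

    v <- momentum * v + g;  w <- w - lr * v.  The learning rate may change
    between steps (polynomial decay is applied per iteration by the trainer).
    """

    def __init__(self, params: List[Parameter], lr: float, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else lr
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data = p.data - lr * v
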