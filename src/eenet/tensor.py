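"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The segmentation network in this package is small enough to train on a single
CPU, so instead of depending on a deep-learning framework the package ships a
compact tensor engine: a :class:`Tensor` wraps an ``ndarray`` and records the
operations applied to it; :meth:`Tensor.backward` walks the recorded graph in
reverse topological order and accumulates gradients into every tensor created
with ``requires_grad=True``.

Only the operations the network needs are implemented (elementwise
arithmetic, batched matmul, reductions, reshapes, slicing, gather-based
reflective padding, valid cross-correlation, and 2x2 max pooling).  All
computation is double precision unless the caller supplies other dtypes.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "softmax",
    "conv2d_valid",
    "maxpool2x2",
    "pad_reflect",
    "take",
    "reflect_indices",
]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over broadcast dimensions so it matches `shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data: np.ndarray = arr
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], Sequence[Optional[np.ndarray]]]] = None

    # ---- basic introspection -------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # ---- graph construction --------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: Tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("called backward on a tensor that does not require grad")
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be a few hundred nodes deep)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype) if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = self.data + other.data
        return Tensor._op(
            out,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = self.data * other.data
        return Tensor._op(
            out,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = self.data / other.data
        return Tensor._op(
            out,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / (other.data ** 2), other.shape),
            ),
        )

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = self.data ** exponent
        return Tensor._op(
            out,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = np.matmul(self.data, other.data)
        a, b = self, other

        def backward(g):
            ga = _unbroadcast(np.matmul(g, b.data.swapaxes(-1, -2)), a.shape)
            gb = _unbroadcast(np.matmul(a.data.swapaxes(-1, -2), g), b.shape)
            return ga, gb

        return Tensor._op(out, (a, b), backward)

    # ---- elementwise functions ------------------------------------------
    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor._op(out, (self,), lambda g: (g * out,))

    def log(self) -> "Tensor":
        return Tensor._op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.data)
        return Tensor._op(out, (self,), lambda g: (g * 0.5 / out,))

    def abs(self) -> "Tensor":
        return Tensor._op(np.abs(self.data), (self,), lambda g: (g * np.sign(self.data),))

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._op(self.data * mask, (self,), lambda g: (g * mask,))

    def clamp(self, lo: float, hi: float) -> "Tensor":
        out = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._op(out, (self,), lambda g: (g * mask,))

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._op(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = 1
            for ax in axes:
                n *= self.shape[ax]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- shape manipulation ----------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        return Tensor._op(self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),))

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._op(self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),))

    def __getitem__(self, idx) -> "Tensor":
        out = self.data[idx]

        def backward(g):
            acc = np.zeros_like(self.data)
            acc[idx] += g
            return (acc,)

        return Tensor._op(out, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-wise (or any-axis) softmax, shift-stabilised, with fused backward."""
    x = as_tensor(x)
    shifted = x.data - np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        inner = np.sum(g * out, axis=axis, keepdims=True)
        return (out * (g - inner),)

    return Tensor._op(out, (x,), backward)


def reflect_indices(n: int, pad: int) -> np.ndarray:
    """Source indices for mirror ("reflect-101") padding of a length-n axis.

    Degenerate axes (n == 1) fall back to edge replication so padding never
    fails for any positive size.
    """
    if n == 1:
        return np.zeros(n + 2 * pad, dtype=np.intp)
    idx = np.arange(-pad, n + pad)
    period = 2 * (n - 1)
    idx = np.mod(idx, period)
    return np.where(idx >= n, period - idx, idx)


def take(x: Tensor, indices: np.ndarray, axis: int) -> Tensor:
    """Differentiable gather along one axis (duplicate indices accumulate)."""
    x = as_tensor(x)
    indices = np.asarray(indices, dtype=np.intp)
    out = np.take(x.data, indices, axis=axis)

    def backward(g):
        acc = np.zeros_like(x.data)
        np.add.at(np.moveaxis(acc, axis, 0), indices, np.moveaxis(g, axis, 0))
        return (acc,)

    return Tensor._op(out, (x,), backward)


def pad_reflect(x: Tensor, pad_h: int, pad_w: int) -> Tensor:
    """Mirror-pad the two trailing (spatial) axes of a (..., H, W) tensor."""
    x = as_tensor(x)
    h, w = x.shape[-2], x.shape[-1]
    if pad_h:
        x = take(x, reflect_indices(h, pad_h), axis=-2)
    if pad_w:
        x = take(x, reflect_indices(w, pad_w), axis=-1)
    return x


def conv2d_valid(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Valid-mode 2-D cross-correlation.

    x: (N, C, H, W); w: (O, C, kh, kw); b: (O,) or None.
    Implemented as a loop over the kh*kw kernel offsets, each a single
    matmul, which keeps both forward and backward BLAS-bound.
    """
    x, w = as_tensor(x), as_tensor(w)
    xd, wd = x.data, w.data
    n, c, h, wdt = xd.shape
    o, c2, kh, kw = wd.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {c2}")
    ho, wo = h - kh + 1, wdt - kw + 1
    if ho < 1 or wo < 1:
        raise ValueError("kernel larger than input; pad first")
    out = np.zeros((n, ho, wo, o), dtype=np.result_type(xd, wd))
    for di in range(kh):
        for dj in range(kw):
            patch = xd[:, :, di : di + ho, dj : dj + wo]
            out += np.tensordot(patch, wd[:, :, di, dj], axes=([1], [1]))
    if b is not None:
        b = as_tensor(b)
        out = out + b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gn = g.transpose(0, 2, 3, 1)  # N, Ho, Wo, O
        gx = np.zeros_like(xd) if x.requires_grad else None
        gw = np.zeros_like(wd) if w.requires_grad else None
        for di in range(kh):
            for dj in range(kw):
                if gx is not None:
                    gx[:, :, di : di + ho, dj : dj + wo] += np.tensordot(
                        gn, wd[:, :, di, dj], axes=([3], [0])
                    ).transpose(0, 3, 1, 2)
                if gw is not None:
                    gw[:, :, di, dj] = np.tensordot(
                        gn, xd[:, :, di : di + ho, dj : dj + wo], axes=([0, 1, 2], [0, 2, 3])
                    )
        if b is None:
            return gx, gw
        gb = gn.sum(axis=(0, 1, 2)) if b.requires_grad else None
        return gx, gw, gb

    return Tensor._op(np.ascontiguousarray(out.transpose(0, 3, 1, 2)), parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; H and W must be even."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dims; pad first")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))

    def backward(g):
        mask = xr == out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        gx = mask * (g[:, :, :, None, :, None] / counts)
        return (gx.reshape(n, c, h, w),)

    return Tensor._op(out, (x,), backward)
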