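"""Minimal reverse-mode automatic differentiation on numpy arrays.

A compact CPU autodiff core sized for small 3D segmentation networks:
tensors carry a value and, when gradients are required, a closure that
propagates the upstream gradient to their parents. The op set is exactly
what a 3D U-Net with Dice/centerline-Dice/lumen losses needs — 3³
convolutions, 2× max-pooling and nearest-neighbor upsampling, channel
concatenation, stride-1 neighborhood extrema (for soft morphology),
element-wise arithmetic, ReLU and sigmoid, and reductions.

Array layout for network ops is channel-first: ``(C, D, H, W)``.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and _grad_enabled
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- graph ------------------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of a scalar tensor into every parameter."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Iterable[Tensor], backward) -> Tensor:
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


# -- element-wise arithmetic (same shape or python scalar) ------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data / b.data

    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data**2), b.data.shape))

    return _make(data, (a, b), backward)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce a gradient back to the (scalar or same) shape of its source."""
    if g.shape == tuple(shape):
        return g
    return np.sum(g).reshape(shape) if np.prod(shape) == 1 else g.reshape(shape)


def tsum(a: Tensor) -> Tensor:
    a = as_tensor(a)
    data = np.array(a.data.sum())

    def backward(g):
        _accum(a, np.full_like(a.data, float(g)))

    return _make(data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        _accum(a, g * mask)

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), backward)


def log(a: Tensor, eps: float = 1e-12) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data + eps)

    def backward(g):
        _accum(a, g / (a.data + eps))

    return _make(data, (a,), backward)


def minimum(a, b) -> Tensor:
    """Element-wise minimum; gradient routed to the winner (ties → a)."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data <= b.data
    data = np.where(take_a, a.data, b.data)

    def backward(g):
        _accum(a, g * take_a)
        _accum(b, g * ~take_a)

    return _make(data, (a, b), backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes of ``(C, D, H, W)``
    with affine scale/shift."""
    ax = (1, 2, 3)
    mu = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gamma.data[:, None, None, None] * xhat + beta.data[:, None, None, None]

    def backward(g):
        if beta.requires_grad:
            _accum(beta, g.sum(axis=ax))
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=ax))
        if x.requires_grad:
            gxhat = g * gamma.data[:, None, None, None]
            m1 = gxhat.mean(axis=ax, keepdims=True)
            m2 = (gxhat * xhat).mean(axis=ax, keepdims=True)
            _accum(x, inv * (gxhat - m1 - xhat * m2))

    return _make(out, (x, gamma, beta), backward)


# -- network ops ------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3³ convolution with zero padding 1 on a ``(C_in, D, H, W)`` tensor."""
    cin, D, H, W = x.shape
    cout = w.shape[0]
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.zeros((cout, D, H, W))
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                seg = xp[:, dz:dz + D, dy:dy + H, dx:dx + W]
                out += np.tensordot(w.data[:, :, dz, dy, dx], seg, axes=([1], [0]))
    out += b.data[:, None, None, None]

    def backward(g):
        if b.requires_grad:
            _accum(b, g.sum(axis=(1, 2, 3)))
        gxp = np.zeros_like(xp) if x.requires_grad else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for dz in range(3):
            for dy in range(3):
                for dx in range(3):
                    seg = xp[:, dz:dz + D, dy:dy + H, dx:dx + W]
                    if gw is not None:
                        gw[:, :, dz, dy, dx] = np.tensordot(g, seg, axes=([1, 2, 3], [1, 2, 3]))
                    if gxp is not None:
                        gxp[:, dz:dz + D, dy:dy + H, dx:dx + W] += np.tensordot(
                            w.data[:, :, dz, dy, dx], g, axes=([0], [0])
                        )
        if gw is not None:
            _accum(w, gw)
        if gxp is not None:
            _accum(x, gxp[:, 1:1 + D, 1:1 + H, 1:1 + W])

    return _make(out, (x, w, b), backward)


def conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1³ (pointwise) convolution; ``w`` has shape ``(C_out, C_in)``."""
    out = np.tensordot(w.data, x.data, axes=([1], [0])) + b.data[:, None, None, None]

    def backward(g):
        if b.requires_grad:
            _accum(b, g.sum(axis=(1, 2, 3)))
        if w.requires_grad:
            _accum(w, np.tensordot(g, x.data, axes=([1, 2, 3], [1, 2, 3])))
        if x.requires_grad:
            _accum(x, np.tensordot(w.data, g, axes=([0], [0])))

    return _make(out, (x, w, b), backward)


def maxpool2(x: Tensor) -> Tensor:
    """2× max-pooling along all spatial axes of ``(C, D, H, W)``."""
    C, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"spatial shape {(D, H, W)} not divisible by 2")
    r = (
        x.data.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(C, D // 2, H // 2, W // 2, 8)
    )
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gr = np.zeros_like(r)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (
            gr.reshape(C, D // 2, H // 2, W // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(C, D, H, W)
        )
        _accum(x, gx)

    return _make(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2× upsampling along all spatial axes."""
    data = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if not x.requires_grad:
            return
        C, D, H, W = x.shape
        _accum(x, g.reshape(C, D, 2, H, 2, W, 2).sum(axis=(2, 4, 6)))

    return _make(data, (x,), backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    data = np.concatenate([a.data, b.data], axis=0)
    ca = a.shape[0]

    def backward(g):
        _accum(a, g[:ca])
        _accum(b, g[ca:])

    return _make(data, (a, b), backward)


def neighbor_extremum(x: Tensor, axis: int, mode: str = "max") -> Tensor:
    """Stride-1 size-3 max/min along one axis; out-of-volume neighbors are
    ignored (±inf padding). Gradient goes to the first winning position."""
    sign = 1.0 if mode == "max" else -1.0
    padval = -np.inf
    nd = x.data.ndim
    pad = [(0, 0)] * nd
    pad[axis] = (1, 1)
    xp = np.pad(sign * x.data, pad, constant_values=padval)
    L = x.data.shape[axis]

    def sl(start):
        s = [slice(None)] * nd
        s[axis] = slice(start, start + L)
        return tuple(s)

    c0, c1, c2 = xp[sl(0)], xp[sl(1)], xp[sl(2)]
    y = np.maximum(np.maximum(c0, c1), c2)

    def backward(g):
        if not x.requires_grad:
            return
        m0 = c0 == y
        m1 = (c1 == y) & ~m0
        m2 = ~(m0 | m1)
        gp = np.zeros_like(xp)
        gp[sl(0)] += g * m0
        gp[sl(1)] += g * m1
        gp[sl(2)] += g * m2
        # the sign applied to x cancels (sign² = 1), so masks route g directly
        _accum(x, gp[sl(1)])

    return _make(sign * y, (x,), backward)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters stay trainable under no_grad


class Adam:
    """Adaptive-moment gradient descent over a parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
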