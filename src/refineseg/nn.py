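"""Minimal reverse-mode automatic differentiation with CNN layers on NumPy.

This module provides exactly the operator set the segmentation and boundary
refinement networks need, in NCHW layout:

* :class:`Tensor` — an ndarray wrapper that records a backward graph,
* elementwise arithmetic, ``sum``/``mean``, clipped ``log``, ``relu``,
* :class:`Conv2d` (stride-1, im2col + GEMM), :class:`BatchNorm2d`,
* ``max_pool2x``, ``upsample_nearest2x``, ``upsample_bilinear2x``,
* channel ``concat`` and channel ``softmax``,
* an :class:`Adam` optimiser and a small :class:`Module` system with
  ``state_dict``/``load_state_dict`` for checkpointing.

Everything is float32 by default (``DTYPE``); gradient-check tests may switch
to float64.  All computation is plain NumPy so the package runs on a single
CPU with no external deep-learning dependency.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _arr(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != DTYPE:
        a = a.astype(DTYPE)
    return a


class Tensor:
    """An ndarray with an optional backward closure.

    ``_backward`` maps the gradient of this tensor to a tuple of gradients,
    one per entry of ``_parents`` (``None`` allowed for non-differentiable
    parents).
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = _arr(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and (p._parents or p.requires_grad):
                    stack.append((p, False))
        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for p, g in zip(node._parents, grads):
                if g is None:
                    continue
                if p.requires_grad or p._parents:
                    p.grad = g if p.grad is None else p.grad + g
            if node is not self:
                node.grad = None  # free intermediate gradients early

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: tuple, backward) -> Tensor:
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        return Tensor(data, False, parents, backward)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def bwd(go):
        return _unbroadcast(go, a.data.shape), _unbroadcast(go, b.data.shape)

    return _make(out, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def bwd(go):
        return (_unbroadcast(go * b.data, a.data.shape),
                _unbroadcast(go * a.data, b.data.shape))

    return _make(out, (a, b), bwd)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data

    def bwd(go):
        ga = _unbroadcast(go / b.data, a.data.shape)
        gb = _unbroadcast(-go * a.data / (b.data * b.data), b.data.shape)
        return ga, gb

    return _make(out, (a, b), bwd)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(go):
        g = np.asarray(go)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return _make(out, (a,), bwd)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in np.atleast_1d(axis)])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    out = a.data.reshape(shape)

    def bwd(go):
        return (go.reshape(old),)

    return _make(out, (a,), bwd)


def log_clipped(a: Tensor, floor: float = 1e-12) -> Tensor:
    """log(max(x, floor)); gradient is zero on the clipped region."""
    a = as_tensor(a)
    clipped = np.maximum(a.data, floor)
    out = np.log(clipped)

    def bwd(go):
        return (np.where(a.data > floor, go / clipped, 0.0),)

    return _make(out, (a,), bwd)


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, 0)

    def bwd(go):
        return (go * (a.data > 0),)

    return _make(out, (a,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(go):
        return tuple(np.array_split(go, splits, axis=axis))

    return _make(out, tuple(tensors), bwd)


def softmax(a: Tensor, axis: int = 1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(go):
        return (s * (go - (go * s).sum(axis=axis, keepdims=True)),)

    return _make(s, (a,), bwd)


def max_pool2x(a: Tensor) -> Tensor:
    a = as_tensor(a)
    n, c, h, w = a.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x needs even spatial dims, got {h}x{w}")
    h2, w2 = h // 2, w // 2
    r = a.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = np.ascontiguousarray(r).reshape(n, c, h2, w2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bwd(go):
        dr = np.zeros((n, c, h2, w2, 4), dtype=go.dtype)
        np.put_along_axis(dr, idx[..., None], go[..., None], axis=-1)
        dx = dr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (np.ascontiguousarray(dx).reshape(n, c, h, w),)

    return _make(out, (a,), bwd)


def upsample_nearest2x(a: Tensor) -> Tensor:
    a = as_tensor(a)
    n, c, h, w = a.data.shape
    out = a.data.repeat(2, axis=2).repeat(2, axis=3)

    def bwd(go):
        return (go.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return _make(out, (a,), bwd)


_bilinear_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _bilinear_coeffs(size: int):
    """Source indices/weights for x2 upsampling, half-pixel-centred sampling."""
    if size not in _bilinear_cache:
        src = (np.arange(2 * size) + 0.5) / 2.0 - 0.5
        s = np.clip(src, 0, size - 1)
        i0 = np.floor(s).astype(np.intp)
        i1 = np.minimum(i0 + 1, size - 1)
        w = (s - i0).astype(DTYPE)
        _bilinear_cache[size] = (i0, i1, w)
    return _bilinear_cache[size]


def _interp_axis2(x: np.ndarray, i0, i1, w):
    wc = w[None, None, :, None].astype(x.dtype)
    return x[:, :, i0, :] * (1.0 - wc) + x[:, :, i1, :] * wc


def _scatter_axis2(go: np.ndarray, in_size: int, i0, i1, w):
    wc = w[None, None, :, None].astype(go.dtype)
    shape = list(go.shape)
    shape[2] = in_size
    g = np.zeros(shape, dtype=go.dtype)
    gm = np.moveaxis(g, 2, 0)
    np.add.at(gm, i0, np.moveaxis(go * (1.0 - wc), 2, 0))
    np.add.at(gm, i1, np.moveaxis(go * wc, 2, 0))
    return g


def upsample_bilinear2x(a: Tensor) -> Tensor:
    a = as_tensor(a)
    n, c, h, w = a.data.shape
    hi0, hi1, hw = _bilinear_coeffs(h)
    wi0, wi1, ww = _bilinear_coeffs(w)
    y = _interp_axis2(a.data, hi0, hi1, hw)                       # rows
    y = _interp_axis2(y.transpose(0, 1, 3, 2), wi0, wi1, ww)      # cols
    out = np.ascontiguousarray(y.transpose(0, 1, 3, 2))

    def bwd(go):
        g = _scatter_axis2(np.ascontiguousarray(go.transpose(0, 1, 3, 2)),
                           w, wi0, wi1, ww)
        g = _scatter_axis2(np.ascontiguousarray(g.transpose(0, 1, 3, 2)),
                           h, hi0, hi1, hw)
        return (g,)

    return _make(out, (a,), bwd)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module system: attribute walking gives parameters and state."""

    def __init__(self):
        self.training = True

    # attribute discovery ----------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # checkpoint -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: np.asarray(b).copy()
                      for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name for name, _ in self.named_buffers()}
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = _arr(value).copy()
            elif name in buffers:
                self._set_buffer(name, value)
            else:
                raise KeyError(f"unexpected state entry {name!r}")
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing state entries: {sorted(missing)}")

    def _set_buffer(self, dotted: str, value) -> None:
        obj: Module = self
        parts = dotted.split(".")
        i = 0
        while i < len(parts) - 1:
            attr = getattr(obj, parts[i])
            if isinstance(attr, (list, tuple)):
                obj = attr[int(parts[i + 1])]
                i += 2
            else:
                obj = attr
                i += 1
        setattr(obj, parts[-1], np.asarray(value, dtype=DTYPE).copy())

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv2d(Module):
    """Stride-1 2-D convolution (kernel 3 with padding 1, or kernel 1)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 padding: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2 if padding is None else padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        std = math.sqrt(2.0 / fan_in)  # He initialisation for ReLU stacks
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, fan_in)))
        self.bias = Parameter(np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        xd = as_tensor(x).data
        n, c, h, w = xd.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}")
        k, p = self.kernel_size, self.padding
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        cout = self.out_channels
        weight, bias = self.weight, self.bias
        if k == 1:
            cols = np.ascontiguousarray(xd.transpose(1, 0, 2, 3)) \
                .reshape(c, n * ho * wo)
            xp = None
        else:
            xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
            # column matrix (C*k*k, N*Ho*Wo) built from k*k shifted slices:
            # long contiguous copies, much faster than an element gather
            cols = np.empty((c, k, k, n, ho, wo), dtype=xd.dtype)
            for ki in range(k):
                for kj in range(k):
                    cols[:, ki, kj] = \
                        xp[:, :, ki:ki + ho, kj:kj + wo].transpose(1, 0, 2, 3)
            cols = cols.reshape(c * k * k, n * ho * wo)
        out = weight.data @ cols
        out += bias.data[:, None]
        if n == 1:
            out = out.reshape(1, cout, ho, wo)
        else:
            out = np.ascontiguousarray(
                out.reshape(cout, n, ho, wo).transpose(1, 0, 2, 3))

        def bwd(go):
            if n == 1:
                g = go.reshape(cout, ho * wo)
            else:
                g = np.ascontiguousarray(go.transpose(1, 0, 2, 3)) \
                    .reshape(cout, n * ho * wo)
            dw = g @ cols.T
            db = g.sum(axis=1)
            dcols = weight.data.T @ g
            if k == 1:
                dx = np.ascontiguousarray(
                    dcols.reshape(c, n, ho, wo).transpose(1, 0, 2, 3))
                return dx, dw, db
            dcols = dcols.reshape(c, k, k, n, ho, wo)
            dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=go.dtype)
            dxp_t = dxp.transpose(1, 0, 2, 3)
            for ki in range(k):
                for kj in range(k):
                    dxp_t[:, :, ki:ki + ho, kj:kj + wo] += dcols[:, ki, kj]
            dx = dxp[:, :, p:p + h, p:p + w] if p else dxp
            return np.ascontiguousarray(dx), dw, db

        return _make(out, (as_tensor(x), weight, bias), bwd)


class BatchNorm2d(Module):
    """Per-channel batch normalisation over (N, H, W)."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        xd = x.data
        if self.training:
            mu = xd.mean(axis=(0, 2, 3))
            var = xd.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (xd - mu[None, :, None, None]) / std[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]
        gamma, beta, training = self.gamma, self.beta, self.training

        def bwd(go):
            dgamma = (go * xhat).sum(axis=(0, 2, 3))
            dbeta = go.sum(axis=(0, 2, 3))
            scale = (gamma.data / std)[None, :, None, None]
            if training:
                gom = go.mean(axis=(0, 2, 3), keepdims=True)
                gxm = (go * xhat).mean(axis=(0, 2, 3), keepdims=True)
                dx = scale * (go - gom - xhat * gxm)
            else:
                dx = scale * go
            return dx, dgamma, dbeta

        return _make(out, (x, gamma, beta), bwd)


class Adam:
    """Adam with bias correction; state keyed by parameter identity order."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
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
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
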