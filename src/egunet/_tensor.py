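"""Reverse-mode automatic differentiation on numpy arrays.

This is the numerical core of the package: a small define-by-run tape with
exactly the operations the segmentation network needs (dense/depthwise 2D
convolution, batch/group normalisation, bilinear upsampling, the usual
activations and elementwise algebra). Gradients are accumulated by a
topological sweep over the recorded graph, in the style of the classic
scalar-autograd teaching implementations but vectorised over ndarrays.

Two execution modes share one functional API:

* ``Tensor`` inputs run real arithmetic and record the backward tape.
* ``ShapeRef`` inputs propagate shapes only; convolution ops report their
  multiply-accumulate counts to an active :class:`MacCounter`. This is what
  the parameter/FLOP budget engine runs on, so counting never needs to touch
  17M-parameter weight arrays.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "ShapeRef", "MacCounter", "no_grad"]

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = (), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this tensor (must be scalar if ``grad`` is None)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = _accum(self.grad, np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node is not self:
                # free intermediate tapes eagerly; parameters keep their grads
                node._backward = None
                node._parents = ()

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


class ShapeRef:
    """Shape-only stand-in for a Tensor, used by the budget counter."""

    __slots__ = ("shape",)

    def __init__(self, shape: Sequence[int]):
        self.shape = tuple(int(s) for s in shape)

    @property
    def ndim(self):
        return len(self.shape)

    def __repr__(self):  # pragma: no cover
        return f"ShapeRef{self.shape}"


class MacCounter:
    """Collects multiply-accumulate counts per scope during a shape-mode pass.

    Scopes are pushed by :class:`egunet.nn.Module`; the counter records the
    full scope path for every conv so budgets can be broken down per block.
    """

    _active: "MacCounter | None" = None

    def __init__(self):
        self.macs_by_scope: dict[str, int] = {}
        self.scope_stack: list[str] = []

    def __enter__(self):
        MacCounter._active = self
        return self

    def __exit__(self, *exc):
        MacCounter._active = None
        return False

    def add(self, macs: int):
        scope = "/".join(self.scope_stack) or "<root>"
        self.macs_by_scope[scope] = self.macs_by_scope.get(scope, 0) + int(macs)

    @property
    def total(self) -> int:
        return sum(self.macs_by_scope.values())


class no_grad:
    """Context manager marker; inference helpers wrap inputs as plain Tensors."""

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


# ---------------------------------------------------------------------------
# helpers


def _accum(current, update):
    if current is None:
        return update.copy() if update.base is not None else update
    current += update
    return current


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _shape_mode(*xs) -> bool:
    return any(isinstance(x, ShapeRef) for x in xs)


def _as_shape(x):
    return x.shape if isinstance(x, (Tensor, ShapeRef)) else np.asarray(x).shape


def constant(data) -> Tensor:
    return Tensor(np.asarray(data))


# ---------------------------------------------------------------------------
# elementwise algebra


def add(a, b):
    if _shape_mode(a, b):
        return ShapeRef(np.broadcast_shapes(_as_shape(a), _as_shape(b)))
    if not isinstance(a, Tensor):
        a = Tensor(a)
    if not isinstance(b, Tensor):
        b = Tensor(np.asarray(b, dtype=a.dtype))
    out = Tensor(a.data + b.data, _parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, _unbroadcast(g, a.shape))
        if b.requires_grad:
            b.grad = _accum(b.grad, _unbroadcast(g, b.shape))

    out._backward = bw
    return out


def mul(a, b):
    if _shape_mode(a, b):
        return ShapeRef(np.broadcast_shapes(_as_shape(a), _as_shape(b)))
    if not isinstance(a, Tensor):
        a = Tensor(a)
    if not isinstance(b, Tensor):
        b = Tensor(np.asarray(b, dtype=a.dtype))
    out = Tensor(a.data * b.data, _parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, _unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.grad = _accum(b.grad, _unbroadcast(g * a.data, b.shape))

    out._backward = bw
    return out


def power(a: Tensor, p: float):
    if _shape_mode(a):
        return ShapeRef(a.shape)
    out = Tensor(a.data ** p, _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g * p * a.data ** (p - 1.0))

    out._backward = bw
    return out


def exp(a: Tensor):
    if _shape_mode(a):
        return ShapeRef(a.shape)
    y = np.exp(a.data)
    out = Tensor(y, _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g * y)

    out._backward = bw
    return out


def log(a: Tensor):
    if _shape_mode(a):
        return ShapeRef(a.shape)
    out = Tensor(np.log(a.data), _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g / a.data)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# activations


def relu(a):
    if _shape_mode(a):
        return ShapeRef(a.shape)
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0.0), _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g * mask)

    out._backward = bw
    return out


def sigmoid(a):
    if _shape_mode(a):
        return ShapeRef(a.shape)
    from scipy.special import expit  # overflow-free logistic

    y = expit(a.data)
    out = Tensor(y, _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g * y * (1.0 - y))

    out._backward = bw
    return out


def tanh(a):
    if _shape_mode(a):
        return ShapeRef(a.shape)
    y = np.tanh(a.data)
    out = Tensor(y, _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g * (1.0 - y * y))

    out._backward = bw
    return out


def gelu(a):
    """Exact (erf-based) Gaussian error linear unit."""
    if _shape_mode(a):
        return ShapeRef(a.shape)
    x = a.data
    phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    out = Tensor(x * phi, _parents=(a,))

    def bw(g):
        if a.requires_grad:
            pdf = np.exp(-0.5 * x * x) * _INV_SQRT2PI
            a.grad = _accum(a.grad, g * (phi + x * pdf))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# shape manipulation


def reshape(a, shape):
    if _shape_mode(a):
        return ShapeRef(np.empty(a.shape, dtype=np.int8).reshape(shape).shape)
    orig = a.shape
    out = Tensor(a.data.reshape(shape), _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g.reshape(orig))

    out._backward = bw
    return out


def transpose(a, axes):
    if _shape_mode(a):
        return ShapeRef(tuple(a.shape[i] for i in axes))
    inv = np.argsort(axes)
    out = Tensor(a.data.transpose(axes), _parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g.transpose(inv))

    out._backward = bw
    return out


def concat(tensors: Sequence, axis: int = 1):
    if any(_shape_mode(t) for t in tensors):
        shapes = [list(_as_shape(t)) for t in tensors]
        out = list(shapes[0])
        out[axis] = sum(s[axis] for s in shapes)
        return ShapeRef(out)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad = _accum(t.grad, g[tuple(sl)])

    out._backward = bw
    return out


def take_channels(a, index: np.ndarray):
    """Permute/select along axis 1 with a fixed integer index (channel shuffle)."""
    if _shape_mode(a):
        return ShapeRef((a.shape[0], len(index)) + tuple(a.shape[2:]))
    index = np.asarray(index)
    out = Tensor(a.data[:, index], _parents=(a,))

    def bw(g):
        if a.requires_grad:
            gx = np.zeros_like(a.data)
            np.add.at(gx, (slice(None), index), g)
            a.grad = _accum(a.grad, gx)

    out._backward = bw
    return out


def reduce_sum(a, axis=None, keepdims=False):
    if _shape_mode(a):
        return ShapeRef(np.sum(np.empty(a.shape, dtype=np.int8), axis=axis, keepdims=keepdims).shape)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,))
    shp = a.shape

    def bw(g):
        if a.requires_grad:
            if axis is None:
                grad = np.broadcast_to(g, shp)
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(ax % len(shp) for ax in axes)
                gk = g if keepdims else np.expand_dims(g, axes)
                grad = np.broadcast_to(gk, shp)
            a.grad = _accum(a.grad, grad)

    out._backward = bw
    return out


def reduce_mean(a, axis=None, keepdims=False):
    if _shape_mode(a):
        return ShapeRef(np.mean(np.empty(a.shape, dtype=np.int8), axis=axis, keepdims=keepdims).shape)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(reduce_sum(a, axis, keepdims), 1.0 / float(n))


# ---------------------------------------------------------------------------
# convolutions


def _conv_out_size(size: int, k: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - k) // stride + 1


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """Dense 2D cross-correlation. x:[N,Cin,H,W], w:[Cout,Cin,kh,kw], b:[Cout]."""
    if _shape_mode(x):
        n, cin, h, wdt = x.shape
        cout, cin_w, kh, kw = _as_shape(w)
        if cin != cin_w:
            raise ValueError(f"conv2d channel mismatch: input {cin}, weight expects {cin_w}")
        ho, wo = _conv_out_size(h, kh, stride, padding), _conv_out_size(wdt, kw, stride, padding)
        if MacCounter._active is not None:
            MacCounter._active.add(n * cout * ho * wo * cin * kh * kw)
        return ShapeRef((n, cout, ho, wo))

    n, cin, h, wdt = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight expects {cin_w}")
    ho, wo = _conv_out_size(h, kh, stride, padding), _conv_out_size(wdt, kw, stride, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = np.empty((n, cin, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    cols2 = cols.reshape(n, cin * kh * kw, ho * wo)
    w2 = w.data.reshape(cout, cin * kh * kw)
    y = np.matmul(w2, cols2).reshape(n, cout, ho, wo)
    if b is not None:
        y += b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _parents=parents)

    def bw(g):
        g2 = g.reshape(n, cout, ho * wo)
        if b is not None and b.requires_grad:
            b.grad = _accum(b.grad, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.einsum("nol,nkl->ok", g2, cols2, optimize=True)
            w.grad = _accum(w.grad, dw.reshape(w.shape))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2).reshape(n, cin, kh, kw, ho, wo)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x.grad = _accum(x.grad, dxp)

    out._backward = bw
    return out


def depthwise_conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """Per-channel 2D cross-correlation. x:[N,C,H,W], w:[C,kh,kw], b:[C]."""
    if _shape_mode(x):
        n, c, h, wdt = x.shape
        c_w, kh, kw = _as_shape(w)
        if c != c_w:
            raise ValueError(f"depthwise conv channel mismatch: {c} vs {c_w}")
        ho, wo = _conv_out_size(h, kh, stride, padding), _conv_out_size(wdt, kw, stride, padding)
        if MacCounter._active is not None:
            MacCounter._active.add(n * c * ho * wo * kh * kw)
        return ShapeRef((n, c, ho, wo))

    n, c, h, wdt = x.shape
    c_w, kh, kw = w.shape
    if c != c_w:
        raise ValueError(f"depthwise conv channel mismatch: {c} vs {c_w}")
    ho, wo = _conv_out_size(h, kh, stride, padding), _conv_out_size(wdt, kw, stride, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    y = np.zeros((n, c, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            y += xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] * w.data[None, :, i, j, None, None]
    if b is not None:
        y += b.data.reshape(1, c, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _parents=parents)

    def bw(g):
        if b is not None and b.requires_grad:
            b.grad = _accum(b.grad, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    sl = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
                    dw[:, i, j] = np.einsum("nchw,nchw->c", sl, g, optimize=True)
            w.grad = _accum(w.grad, dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g * w.data[None, :, i, j, None, None]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x.grad = _accum(x.grad, dxp)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# normalisation


def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.1, eps: float = 1e-5):
    """Batch normalisation over (N, H, W) per channel with running statistics."""
    if _shape_mode(x):
        return ShapeRef(x.shape)
    n, c = x.shape[0], x.shape[1]
    if training:
        m = x.data.size // c
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        unbiased = var * (m / max(m - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        m = None
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    y = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
    out = Tensor(y, _parents=(x, gamma, beta))

    def bw(g):
        if beta.requires_grad:
            beta.grad = _accum(beta.grad, g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma.grad = _accum(gamma.grad, (g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = g * gamma.data[None, :, None, None]
            if training:
                s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (dxhat - s1 / m - xhat * s2 / m) * inv_std[None, :, None, None]
            else:
                dx = dxhat * inv_std[None, :, None, None]
            x.grad = _accum(x.grad, dx)

    out._backward = bw
    return out


def group_norm(x, gamma, beta, groups: int, eps: float = 1e-5):
    """Group normalisation over (C/G, H, W) per (sample, group)."""
    if _shape_mode(x):
        if x.shape[1] % groups:
            raise ValueError(f"group_norm: {x.shape[1]} channels not divisible by {groups} groups")
        return ShapeRef(x.shape)
    n, c, h, wdt = x.shape
    if c % groups:
        raise ValueError(f"group_norm: {c} channels not divisible by {groups} groups")
    xg = x.data.reshape(n, groups, -1)
    m = xg.shape[-1]
    mu = xg.mean(axis=-1, keepdims=True)
    var = xg.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv_std).reshape(n, c, h, wdt)
    y = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
    out = Tensor(y, _parents=(x, gamma, beta))

    def bw(g):
        if beta.requires_grad:
            beta.grad = _accum(beta.grad, g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma.grad = _accum(gamma.grad, (g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = (g * gamma.data[None, :, None, None]).reshape(n, groups, -1)
            xh = xhat.reshape(n, groups, -1)
            s1 = dxhat.sum(axis=-1, keepdims=True)
            s2 = (dxhat * xh).sum(axis=-1, keepdims=True)
            dx = (dxhat - s1 / m - xh * s2 / m) * inv_std
            x.grad = _accum(x.grad, dx.reshape(n, c, h, wdt))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# resampling / pooling


def _bilinear_coeffs(size_out: int, size_in: int, dtype):
    # half-pixel (align_corners=False) source coordinates
    src = (np.arange(size_out, dtype=np.float64) + 0.5) * (size_in / size_out) - 0.5
    src = np.clip(src, 0.0, size_in - 1.0)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, size_in - 1)
    t = (src - i0).astype(dtype)
    return i0, i1, t


def upsample_bilinear(x, scale: int = 2):
    """Bilinear upsampling with half-pixel centres (align_corners=False)."""
    if _shape_mode(x):
        n, c, h, w = x.shape
        return ShapeRef((n, c, h * scale, w * scale))
    n, c, h, w = x.shape
    ho, wo = h * scale, w * scale
    i0, i1, ti = _bilinear_coeffs(ho, h, x.dtype)
    j0, j1, tj = _bilinear_coeffs(wo, w, x.dtype)
    rows = x.data[:, :, i0, :] * (1.0 - ti)[None, None, :, None] + x.data[:, :, i1, :] * ti[None, None, :, None]
    y = rows[:, :, :, j0] * (1.0 - tj)[None, None, None, :] + rows[:, :, :, j1] * tj[None, None, None, :]
    out = Tensor(y, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            drows = np.zeros((n, c, ho, w), dtype=g.dtype)
            np.add.at(drows, (slice(None), slice(None), slice(None), j0), g * (1.0 - tj)[None, None, None, :])
            np.add.at(drows, (slice(None), slice(None), slice(None), j1), g * tj[None, None, None, :])
            dx = np.zeros_like(x.data)
            np.add.at(dx, (slice(None), slice(None), i0, slice(None)), drows * (1.0 - ti)[None, None, :, None])
            np.add.at(dx, (slice(None), slice(None), i1, slice(None)), drows * ti[None, None, :, None])
            x.grad = _accum(x.grad, dx)

    out._backward = bw
    return out


def global_avg_pool(x):
    """[N,C,H,W] -> [N,C,1,1] mean pooling."""
    if _shape_mode(x):
        return ShapeRef((x.shape[0], x.shape[1], 1, 1))
    return reduce_mean(x, axis=(2, 3), keepdims=True)


# ---------------------------------------------------------------------------
# composite heads


def log_softmax(x, axis: int = 1):
    if _shape_mode(x):
        return ShapeRef(x.shape)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # detached for stability
    z = add(x, mul(shift, -1.0))
    return add(z, mul(log(reduce_sum(exp(z), axis=axis, keepdims=True)), -1.0))


def softmax(x, axis: int = 1):
    if _shape_mode(x):
        return ShapeRef(x.shape)
    return exp(log_softmax(x, axis))
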