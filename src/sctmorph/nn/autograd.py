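"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for a small convolutional encoder-decoder GAN trained
on the CPU: tensors carry a backward closure and parent links; ``backward``
runs the tape in reverse topological order. Only the ops the synthesis
network needs are provided (conv2d via im2col, nearest upsampling, instance
normalization, dropout, channel concat, dense layers and the pointwise
nonlinearities). Shapes follow the (N, C, H, W) convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_grad_fn", "requires_grad")

    def __init__(self, data, parents=(), grad_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._grad_fn = grad_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._grad_fn is None:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._grad_fn(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        return Tensor(self.data + other.data, (self, other), lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        return Tensor(
            self.data * other.data,
            (self, other),
            lambda g: (_unbroadcast(g * other.data, self.data.shape), _unbroadcast(g * self.data, other.data.shape)),
        )

    __rmul__ = __mul__

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(grad, shape):
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# pointwise / reduction ops
# ---------------------------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    y = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-x.data)), np.exp(x.data) / (1.0 + np.exp(x.data)))
    return Tensor(y, (x,), lambda g: (g * y * (1.0 - y),))


def softplus(x: Tensor) -> Tensor:
    y = np.logaddexp(0.0, x.data)
    s = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-x.data)), np.exp(x.data) / (1.0 + np.exp(x.data)))
    return Tensor(y, (x,), lambda g: (g * s,))


def absolute(x: Tensor) -> Tensor:
    s = np.sign(x.data)
    return Tensor(np.abs(x.data), (x,), lambda g: (g * s,))


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.data), (x,), lambda g: (g / x.data,))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    mask = (x.data > lo) & (x.data < hi)
    return Tensor(np.clip(x.data, lo, hi), (x,), lambda g: (g * mask,))


def mean(x: Tensor) -> Tensor:
    n = x.data.size
    shape = x.data.shape
    return Tensor(x.data.mean(), (x,), lambda g: (np.broadcast_to(g / n, shape).copy(),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def grad_fn(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return (y * (g - dot),)

    return Tensor(y, (x,), grad_fn)


def gather_rows(x: Tensor, idx) -> Tensor:
    """x[i, idx[i]] for a 2D tensor; used for class-probability lookups."""
    idx = np.asarray(idx, dtype=np.int64)
    rows = np.arange(x.data.shape[0])

    def grad_fn(g):
        out = np.zeros_like(x.data)
        out[rows, idx] = g
        return (out,)

    return Tensor(x.data[rows, idx], (x,), grad_fn)


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate(datas, axis=axis), tuple(tensors), grad_fn)


def matmul(x: Tensor, w: Tensor) -> Tensor:
    return Tensor(x.data @ w.data, (x, w), lambda g: (g @ w.data.T, x.data.T @ g))


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return Tensor(x.data * keep, (x,), lambda g: (g * keep,))


# ---------------------------------------------------------------------------
# spatial ops (N, C, H, W)
# ---------------------------------------------------------------------------


def _im2col(x, k, s, p):
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    n, c, h, w = x.shape
    ho, wo = (h - k) // s + 1, (w - k) // s + 1
    st = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, ho, wo), (st[0], st[1], st[2], st[3], st[2] * s, st[3] * s)
    )
    return np.ascontiguousarray(cols).reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(cols, xshape, k, s, p, ho, wo):
    n, c, h, w = xshape
    hp, wp = h + 2 * p, w + 2 * p
    out = np.zeros((n, c, hp, wp))
    cols6 = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + s * ho : s, j : j + s * wo : s] += cols6[:, :, i, j]
    return out[:, :, p : p + h, p : p + w] if p else out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, padding: int = 1) -> Tensor:
    """2D convolution; weight (O, C, k, k), bias (O,)."""
    o, c, k, _ = weight.data.shape
    cols, ho, wo = _im2col(x.data, k, stride, padding)
    n = x.data.shape[0]
    wmat = weight.data.reshape(o, -1)
    out = np.matmul(wmat, cols) + bias.data[None, :, None]
    out = out.reshape(n, o, ho, wo)
    xshape = x.data.shape

    def grad_fn(g):
        gmat = g.reshape(n, o, ho * wo)
        dw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(weight.data.shape)
        db = gmat.sum(axis=(0, 2))
        dcols = np.matmul(wmat.T, gmat)
        dx = _col2im(dcols, xshape, k, stride, padding, ho, wo)
        return dx, dw, db

    return Tensor(out, (x, weight, bias), grad_fn)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def grad_fn(g):
        n, c, h, w = g.shape
        return (g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)),)

    return Tensor(out, (x,), grad_fn)


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape

    def grad_fn(g):
        return (np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).copy(),)

    return Tensor(x.data.mean(axis=(2, 3)), (x,), grad_fn)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each (sample, channel) over its spatial extent, then apply
    a per-channel affine map."""
    axes = (2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gcol = gamma.data[None, :, None, None]
    out = gcol * xhat + beta.data[None, :, None, None]
    m = x.data.shape[2] * x.data.shape[3]

    def grad_fn(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        dxhat = g * gcol
        dx = inv * (dxhat - dxhat.mean(axis=axes, keepdims=True) - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        return dx, dgamma, dbeta

    return Tensor(out, (x, gamma, beta), grad_fn)
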