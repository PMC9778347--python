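"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations the segmentation and autoencoder networks need are
implemented.  A :class:`Tensor` wraps a float32 ndarray and records, for each
producing operation, its parents together with closures that map the output
gradient to each parent gradient.  ``backward()`` runs a topological sweep.

Convolution, pooling and batch-norm live in :mod:`fetalbrain.nn.layers` as
fused primitives built with :func:`make_op`; everything here is elementwise,
reduction or linear algebra.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # ------------------------------------------------------------------ graph
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
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
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                if not parent.requires_grad:
                    continue
                pg = fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        return None

    # ------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def make_op(data: np.ndarray, parents) -> Tensor:
    """Create a graph node.  ``parents`` is a list of ``(Tensor, grad_fn)``."""
    parents = [(p, fn) for p, fn in parents if isinstance(p, Tensor)]
    out = Tensor(data, requires_grad=any(p.requires_grad for p, _ in parents))
    if out.requires_grad:
        out._parents = tuple(parents)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# --------------------------------------------------------------- elementwise
def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return make_op(
        a.data + b.data,
        [(a, lambda g: _unbroadcast(g, a.data.shape)),
         (b, lambda g: _unbroadcast(g, b.data.shape))],
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return make_op(
        a.data * b.data,
        [(a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
         (b, lambda g: _unbroadcast(g * a.data, b.data.shape))],
    )


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return make_op(
        a.data / b.data,
        [(a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
         (b, lambda g: _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))],
    )


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return make_op(a.data * mask, [(a, lambda g: g * mask)])


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = _stable_sigmoid(a.data)
    return make_op(s, [(a, lambda g: g * s * (1.0 - s))])


def swish(a: Tensor) -> Tensor:
    """The activation x * sigmoid(x)."""
    s = _stable_sigmoid(a.data)
    out = a.data * s
    return make_op(out, [(a, lambda g: g * (s + out * (1.0 - s)))])


def log(a: Tensor) -> Tensor:
    return make_op(np.log(a.data), [(a, lambda g: g / a.data)])


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)
    return make_op(e, [(a, lambda g: g * e)])


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    mask = (a.data >= lo) & (a.data <= hi)
    return make_op(np.clip(a.data, lo, hi), [(a, lambda g: g * mask)])


# ---------------------------------------------------------------- reductions
def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def back(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).astype(np.float32)
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        return np.broadcast_to(gg, a.data.shape).astype(np.float32)

    return make_op(out, [(a, back)])


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    s = tsum(a, axis=axis, keepdims=keepdims)
    return mul(s, 1.0 / n)


def tmax(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    out = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out)
    counts = mask.sum(axis=axis, keepdims=True)

    def back(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        return (mask * (gg / counts)).astype(np.float32)

    return make_op(out if keepdims else out.squeeze(axis), [(a, back)])


# ------------------------------------------------------------ shape plumbing
def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return make_op(a.data.reshape(shape), [(a, lambda g: g.reshape(old))])


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def make_back(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return make_op(out, [(t, make_back(i)) for i, t in enumerate(tensors)])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def back_a(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        return _unbroadcast(ga, a.data.shape)

    def back_b(g):
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(gb, b.data.shape)

    return make_op(out, [(a, back_a), (b, back_b)])
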