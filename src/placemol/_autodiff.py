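"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only what the generative model needs: dense float64 tensors, broadcasting
elementwise arithmetic, 2d matrix products, integer-array indexing (embedding
lookups), reductions, `logsumexp` (the numerically safe primitive behind every
softmax/log-softmax in the model) and the shifted-softplus nonlinearity.

Gradients flow into parameters only; geometric inputs (positions, distances)
enter as constants, so no derivatives w.r.t. coordinates are ever formed.
"""

from __future__ import annotations

import contextlib
from typing import Iterable

import numpy as np

__all__ = ["Tensor", "no_grad", "ssp", "logsumexp", "concat", "Adam"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (used during sampling, where only forward
    evaluations are needed)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = _parents
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _make(self, data, parents, backward):
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track,
                     _parents=parents if track else ())
        if track:
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._acc(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._acc(_unbroadcast(g, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._acc(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._acc(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._acc(_unbroadcast(g * a.data, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._acc(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._acc(_unbroadcast(-g * a.data / b.data ** 2, b.data.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._acc(g @ b.data.T)
            if b.requires_grad:
                b._acc(a.data.T @ g)

        return self._make(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g, a=self):
            if a.requires_grad:
                a._acc(g * p * a.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._acc(g * od)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g, a=self):
            if a.requires_grad:
                a._acc(g / a.data)

        return self._make(out_data, (self,), backward)

    # -- shaping --------------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g, a=self, old=old):
            if a.requires_grad:
                a._acc(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._acc(full)

        return self._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._acc(np.broadcast_to(g, a.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._acc(np.broadcast_to(g, a.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- autograd driver ------------------------------------------------------
    def _acc(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


# -- functional ops -----------------------------------------------------------

def ssp(x: Tensor) -> Tensor:
    """Shifted softplus ln(e^x/2 + 1/2) = softplus(x) - ln 2, stable for |x| large."""
    x = Tensor.as_tensor(x)
    out_data = np.logaddexp(0.0, x.data) - np.log(2.0)

    def backward(g, a=x):
        if a.requires_grad:
            a._acc(g / (1.0 + np.exp(-a.data)))

    return x._make(out_data, (x,), backward)


def logsumexp(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Stable log-sum-exp; gradient is the softmax along `axis`."""
    x = Tensor.as_tensor(x)
    m = np.max(x.data, axis=axis, keepdims=True)
    s = np.exp(x.data - m).sum(axis=axis, keepdims=True)
    out_data = m + np.log(s)
    soft = np.exp(x.data - out_data)
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def backward(g, a=x, soft=soft, axis=axis, keepdims=keepdims):
        if a.requires_grad:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._acc(g * soft)

    return x._make(out_data, (x,), backward)


def log_softmax(x: Tensor, axis: int) -> Tensor:
    return x - logsumexp(x, axis=axis, keepdims=True)


def softmax(x: Tensor, axis: int) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, ts=ts, splits=splits, axis=axis):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._acc(piece)

    track = _GRAD_ENABLED and any(t.requires_grad for t in ts)
    out = Tensor(out_data, requires_grad=track,
                 _parents=tuple(ts) if track else ())
    if track:
        out._backward = backward
    return out


class Adam:
    """Adaptive-moment stochastic gradient descent over a name->Tensor mapping."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
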