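"""Minimal vectorized reverse-mode automatic differentiation.

A small tensor engine sufficient for the generative-mechanism and
attention-classifier training loops in this package: dense ndarray
values, a dynamically built tape, and gradients for the handful of
primitives those models need (broadcasting arithmetic, batched matmul,
tanh/exp/log, reductions, static slicing, concatenation).

Gradients accumulate into ``Tensor.grad`` after calling ``backward()``
on a scalar.  Broadcasting is handled by summing gradients over
broadcast axes back to the original shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "SGD", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=float), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            self._accum(g)
            other._accum(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bwd(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = bwd
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y**2))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            g = np.asarray(g, dtype=float)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accum(np.asarray(g).reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(np.transpose(self.data, axes), _prev=(self,))
        inv = np.argsort(axes) if axes else None
        out._backward = lambda g: self._accum(np.transpose(g, inv))
        return out

    def slice(self, idx):
        """Static slice; gradient scatters back into a zero array."""
        out = Tensor(self.data[idx], _prev=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        out._backward = bwd
        return out

    # -- stable softmax helpers -------------------------------------------
    def softmax(self, axis=-1):
        m = np.max(self.data, axis=axis, keepdims=True)  # constant shift
        e = (self - m).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis=-1, keepdims=False):
        m = np.max(self.data, axis=axis, keepdims=True)
        s = (self - m).exp().sum(axis=axis, keepdims=True).log() + m
        return s if keepdims else s.reshape(*np.squeeze(s.data, axis=axis).shape)

    # -- autodiff driver ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(lo), int(hi))
            t._accum(g[tuple(idx)])

    out._backward = bwd
    return out


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self._t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self._t)
            vhat = v / (1 - self.b2**self._t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
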