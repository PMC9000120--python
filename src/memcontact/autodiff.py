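"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the two small networks in this package: dense
and convolutional layers (convolution is expressed as gather + matmul),
gated recurrence, sigmoid/tanh/relu nonlinearities, and sum-style losses.
Gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self):
        """Backpropagate from this (scalar) tensor."""
        topo, visited = [], set()

        def visit(t):
            if id(t) in visited:
                return
            visited.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    def pow(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def sqrt(self):
        return self.pow(0.5)

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- nonlinearities ------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, parents=(self,))

        def backward(g):
            self._accumulate(g * s * (1 - s))

        out._backward = backward
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))

        def backward(g):
            self._accumulate(g * (1 - t * t))

        out._backward = backward
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def backward(g):
            self._accumulate(g * mask)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def backward(g):
            self._accumulate(g / self.data)

        out._backward = backward
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes) if axes else None

        def backward(g):
            self._accumulate(g.transpose(*inv) if inv is not None else g.T)

        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        out._backward = backward
        return out

    def gather_rows(self, idx: np.ndarray):
        """Select rows along axis 0; gradient scatters with accumulation."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = backward
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


def parameter(rng: np.random.Generator, shape: tuple, fan_in: Optional[int] = None) -> Tensor:
    """Glorot-style uniform initialization."""
    if fan_in is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1] if len(shape) > 1 else shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, shape), requires_grad=True)


def zeros_param(shape: tuple) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def l2_penalty(params: dict) -> Tensor:
    """Sum of squared parameter entries (the L2 regularization term)."""
    total = None
    for p in params.values():
        term = p.pow(2.0).sum()
        total = term if total is None else total + term
    return total if total is not None else Tensor(0.0)


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
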