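"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the graph autoencoder needs: broadcasting
arithmetic, matrix products, the activations used by the network (ReLU,
LeakyReLU, ELU), log/reciprocal for the Student-t soft assignment, reductions,
head concatenation, and a masked row-softmax for graph attention. Gradients
accumulate into ``Tensor.grad`` after calling :meth:`Tensor.backward` on a
scalar output.

The engine is deliberately tiny and full-batch oriented; it trades generality
for being easy to verify (every op is finite-difference checked in the test
suite).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "masked_softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(g.T)

        return self._make(self.data.T, (self,), backward)

    def square(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(2.0 * self.data * g)

        return self._make(self.data ** 2, (self,), backward)

    def reciprocal(self) -> "Tensor":
        inv = 1.0 / self.data

        def backward(g: np.ndarray) -> None:
            self._accumulate(-g * inv * inv)

        return self._make(inv, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- activations ----------------------------------------------------------
    def relu(self) -> "Tensor":
        out = np.maximum(self.data, 0.0)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * (self.data > 0))

        return self._make(out, (self,), backward)

    def leaky_relu(self, alpha: float = 0.2) -> "Tensor":
        out = np.where(self.data > 0, self.data, alpha * self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * np.where(self.data > 0, 1.0, alpha))

        return self._make(out, (self,), backward)

    def elu(self, alpha: float = 1.0) -> "Tensor":
        em1 = alpha * np.expm1(np.minimum(self.data, 0.0))
        out = np.where(self.data > 0, self.data, em1)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * np.where(self.data > 0, 1.0, em1 + alpha))

        return self._make(out, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- tape -----------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward(t.grad)

    def item(self) -> float:
        return float(self.data)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (used to merge attention heads)."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    grads_needed = [t for t in tensors if t.requires_grad]
    if grads_needed:
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g: np.ndarray) -> None:
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(idx)])

        out.requires_grad = True
        out._parents = tuple(grads_needed)
        out._backward = backward
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to ``mask`` (boolean); masked entries are 0.

    Every row must have at least one unmasked entry (graph attention always
    includes the self edge, so this holds by construction).
    """
    neg = np.finfo(scores.data.dtype).min
    x = np.where(mask, scores.data, neg)
    x = x - x.max(axis=1, keepdims=True)
    e = np.exp(x) * mask
    s = e.sum(axis=1, keepdims=True)
    p = e / s

    def backward(g: np.ndarray) -> None:
        inner = (g * p).sum(axis=1, keepdims=True)
        scores._accumulate(p * (g - inner))

    out = Tensor(p)
    if scores.requires_grad:
        out.requires_grad = True
        out._parents = (scores,)
        out._backward = backward
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
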