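"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the heterograph network needs: dense and
sparse-constant matrix products, broadcast add/multiply/divide, relu, exp,
concatenation, and reductions.  Gradients are accumulated by a reverse
topological sweep.  Sparse left operands (graph aggregation matrices) are
treated as constants — they encode fixed connectivity, not parameters.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp


class Tensor:
    __slots__ = ("value", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, value, parents=(), backward_fn=None, requires_grad=False):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    # -- graph traversal -------------------------------------------------
    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    def _accumulate(self, g):
        self.grad = g if self.grad is None else self.grad + g

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, constant(-1.0)))

    def __matmul__(self, other):
        return matmul(self, other)

    def __truediv__(self, other):
        return div(self, other)


def parameter(value):
    return Tensor(np.array(value, dtype=float), requires_grad=True)


def constant(value):
    return Tensor(value)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else constant(x)


def _unbroadcast(grad, shape):
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.value + b.value, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.value.shape))

    out.backward_fn = bw
    return out


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.value * b.value, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.value, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.value, b.value.shape))

    out.backward_fn = bw
    return out


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.value / b.value, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.value, a.value.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.value / (b.value**2), b.value.shape))

    out.backward_fn = bw
    return out


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.value @ b.value, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g @ b.value.T)
        if b.requires_grad:
            b._accumulate(a.value.T @ g)

    out.backward_fn = bw
    return out


def spmm(s, a):
    """Sparse-constant @ Tensor. ``s`` is a scipy sparse matrix."""
    if not sp.issparse(s):
        raise TypeError("spmm expects a scipy sparse left operand")
    a = _as_tensor(a)
    out = Tensor(s @ a.value, (a,))
    st = s.T.tocsr()

    def bw(g):
        if a.requires_grad:
            a._accumulate(st @ g)

    out.backward_fn = bw
    return out


def relu(a):
    a = _as_tensor(a)
    mask = a.value > 0
    out = Tensor(np.where(mask, a.value, 0.0), (a,))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    out.backward_fn = bw
    return out


def exp(a):
    a = _as_tensor(a)
    out = Tensor(np.exp(a.value), (a,))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * out.value)

    out.backward_fn = bw
    return out


def concat(tensors, axis=1):
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out.backward_fn = bw
    return out


def mean(a):
    a = _as_tensor(a)
    out = Tensor(np.mean(a.value), (a,))

    def bw(g):
        if a.requires_grad:
            a._accumulate(np.full_like(a.value, float(g) / a.value.size))

    out.backward_fn = bw
    return out


def gather_rows(a, idx):
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=int)
    out = Tensor(a.value[idx], (a,))

    def bw(g):
        if a.requires_grad:
            acc = np.zeros_like(a.value)
            np.add.at(acc, idx, g)
            a._accumulate(acc)

    out.backward_fn = bw
    return out


class Adam:
    """Adam optimizer with decoupled weight decay over parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.value -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.value
            )
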