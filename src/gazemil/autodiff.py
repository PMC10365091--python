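"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations producing
it; :meth:`Tensor.backward` runs reverse-mode accumulation over the
recorded tape. Only the primitives the package's networks and losses
need are provided (elementwise arithmetic, broadcasting, reductions,
sigmoid/softplus family, concatenation, reshaping); convolution and the
other structured layers live in :mod:`gazemil.nn` as fused custom ops
built on the same tape. Gradient correctness is checked against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, log_expit


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the tape bookkeeping for reverse-mode autodiff."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- graph execution ------------------------------------------------
    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every graph leaf."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=self.value.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.value.shape)
        if self.grad is None:
            self.grad = grad.astype(self.value.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a._accumulate(g)
            b._accumulate(g)

        return Tensor(self.value + other.value, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a._accumulate(g * b.value)
            b._accumulate(g * a.value)

        return Tensor(self.value * other.value, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __neg__(self):
        def bw(g, a=self):
            a._accumulate(-g)

        return Tensor(-self.value, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a._accumulate(g / b.value)
            b._accumulate(-g * a.value / (b.value**2))

        return Tensor(self.value / other.value, parents=(self, other), backward=bw)

    def __pow__(self, exponent: float):
        def bw(g, a=self, e=exponent):
            a._accumulate(g * e * a.value ** (e - 1))

        return Tensor(self.value**exponent, parents=(self,), backward=bw)

    # -- shaping --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g, a=self):
            a._accumulate(g.reshape(a.value.shape))

        return Tensor(self.value.reshape(shape), parents=(self,), backward=bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g, a=self, inv=tuple(inv)):
            a._accumulate(g.transpose(inv))

        return Tensor(self.value.transpose(axes), parents=(self,), backward=bw)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g, a=self, axis=axis, keepdims=keepdims):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.value.shape))

        return Tensor(
            self.value.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bw
        )

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else np.prod(
            [self.value.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_val = np.exp(self.value)

        def bw(g, a=self, v=out_val):
            a._accumulate(g * v)

        return Tensor(out_val, parents=(self,), backward=bw)

    def log(self):
        def bw(g, a=self):
            a._accumulate(g / a.value)

        return Tensor(np.log(self.value), parents=(self,), backward=bw)

    def sigmoid(self):
        s = expit(self.value)

        def bw(g, a=self, s=s):
            a._accumulate(g * s * (1.0 - s))

        return Tensor(s, parents=(self,), backward=bw)

    def softplus(self):
        """log(1 + exp(x)), overflow-safe."""
        out_val = np.logaddexp(0.0, self.value)
        s = expit(self.value)

        def bw(g, a=self, s=s):
            a._accumulate(g * s)

        return Tensor(out_val, parents=(self,), backward=bw)

    def log_sigmoid(self):
        out_val = log_expit(self.value)
        s1 = expit(-self.value)  # 1 - sigmoid(x), stable

        def bw(g, a=self, s1=s1):
            a._accumulate(g * s1)

        return Tensor(out_val, parents=(self,), backward=bw)

    def relu(self):
        mask = self.value > 0

        def bw(g, a=self, mask=mask):
            a._accumulate(g * mask)

        return Tensor(np.where(mask, self.value, 0.0), parents=(self,), backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g, ts=tensors, offsets=offsets, axis=axis):
        for t, o0, o1 in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(o0, o1)
            t._accumulate(g[tuple(idx)])

    return Tensor(
        np.concatenate([t.value for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bw,
    )


def custom_op(value: np.ndarray, parents: tuple, backward) -> Tensor:
    """Build a tape node for a fused operation with a hand-written backward.

    ``backward(g)`` must call ``parent._accumulate(...)`` for every
    differentiable parent.
    """
    return Tensor(value, parents=parents, backward=backward)
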