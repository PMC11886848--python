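"""Minimal reverse-mode automatic differentiation over numpy arrays.

The denoising network is small (a few thousand parameters, molecules of at
most a few dozen atoms), so a straightforward define-by-run tape over
float64 numpy arrays is fast enough for desk-scale training and keeps the
whole model dependency-free.  Only the operations the network actually uses
are implemented; gradients are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "log_softmax", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the autodiff tape, wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- basic introspection --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(
            self.data + other.data,
            (self, other),
            lambda g: (g, g),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor._from_op(
            self.data * other.data,
            (self, other),
            lambda g: (g * other.data, g * self.data),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor._from_op(
            self.data / other.data,
            (self, other),
            lambda g: (g / other.data, -g * self.data / other.data**2),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        return Tensor._from_op(
            self.data**p,
            (self,),
            lambda g: (g * p * self.data ** (p - 1),),
        )

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                a2 = a[None, :]
            else:
                a2 = a
            if b.ndim == 1:
                ga = np.outer(g, b) if a.ndim > 1 else g * b
                gb = a2.swapaxes(-1, -2) @ g if a.ndim > 1 else a * g
            else:
                g2 = g[None, :] if a.ndim == 1 else g
                ga = g2 @ b.swapaxes(-1, -2)
                if a.ndim == 1:
                    ga = ga[0]
                gb = a2.swapaxes(-1, -2) @ g2
            return (_unbroadcast(np.asarray(ga), a.shape), _unbroadcast(np.asarray(gb), b.shape))

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def silu(self):
        return self * self.sigmoid()

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._from_op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(self.data.shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._from_op(self.data[idx], (self,), backward)

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
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
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad and g is not None:
                    parent._accumulate(g)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis` with gradient routing."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(data, tensors, backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shift by the (detached) max for numerical stability; constant shift
    # does not change the gradient
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()
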