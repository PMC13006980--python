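"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The model is small (a few dozen parameter matrices, batches of tens of
samples), so a lightweight float64 tape is preferable to a heavyweight
framework: it keeps the dependency footprint to NumPy, makes every forward
pass bit-reproducible, and lets finite-difference gradient checks run at
double precision.

Only the operations the survival network needs are implemented.  All
gradients follow the convention ``parent.grad += d(out)/d(parent) @ out.grad``
with broadcasting resolved by summing over broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "softmax",
    "layer_norm",
    "relu",
    "sigmoid",
    "clip",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A float64 array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for parent in node._parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            out_grad = grads.pop(id(node), None)
            if out_grad is None:
                continue
            if node._backward is None:  # leaf
                node.grad = out_grad if node.grad is None else node.grad + out_grad
                continue
            for parent, pgrad in zip(node._parents, node._backward(out_grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if parent._backward is None and parent._parents == ():
                    parent.grad = pgrad if parent.grad is None else parent.grad + pgrad
                else:
                    grads[key] = pgrad if key not in grads else grads[key] + pgrad

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        return self._node(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return self._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return self._node(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self._node(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return self._node(np.matmul(self.data, other.data), (self, other), backward)

    def __pow__(self, exponent: float):
        return self._node(
            self.data**exponent,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    # -- reductions and reshaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return self._node(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(self.shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        return self._node(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inverse),)
        )

    # -- elementwise nonlinearities -------------------------------------------

    def log(self):
        return self._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    def exp(self):
        out_data = np.exp(self.data)
        return self._node(out_data, (self,), lambda g: (g * out_data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._node(out_data, (self,), lambda g: (g / (2.0 * out_data),))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._node(np.where(mask, x.data, 0.0), (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._node(out_data, (x,), lambda g: (g * out_data * (1.0 - out_data),))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with zero gradient outside [lo, hi] (used for hazard epsilons)."""
    inside = (x.data >= lo) & (x.data <= hi)
    return Tensor._node(np.clip(x.data, lo, hi), (x,), lambda g: (g * inside,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return (y * (g - dot),)

    return Tensor._node(y, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis, composed from primitives."""
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return centred * inv * gamma + beta
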