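"""A minimal reverse-mode automatic-differentiation tensor on NumPy arrays.

Supports the operations the package's encoders and heads need: broadcasted
arithmetic, (batched) matmul, elementwise nonlinearities, reductions,
reshape/transpose/concatenate, and gather-style indexing.  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` via a reverse
topological sweep.  All computation is float64 and fully deterministic.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
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
    """An n-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[Array], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward
        self.name = name

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> Array:
        return self.data

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # leaves collected above; intermediate grads discarded

    # -- arithmetic ----------------------------------------------------------
    def _binary(self, other, fwd, bwd) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = fwd(self.data, other.data)
        a, b = self, other

        def backward(g: Array):
            ga, gb = bwd(g, a.data, b.data)
            return (
                (a, _unbroadcast(ga, a.shape)),
                (b, _unbroadcast(gb, b.shape)),
            )

        return Tensor(out_data, _parents=(a, other), _backward=backward)

    def __add__(self, other):
        return self._binary(other, lambda x, y: x + y, lambda g, x, y: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda x, y: x - y, lambda g, x, y: (g, -g))

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        return self._binary(other, lambda x, y: x * y, lambda g, x, y: (g * y, g * x))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(
            other,
            lambda x, y: x / y,
            lambda g, x, y: (g / y, -g * x / (y * y)),
        )

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __neg__(self):
        a = self
        return Tensor(-a.data, _parents=(a,), _backward=lambda g: ((a, -g),))

    def __pow__(self, exponent: float):
        a = self
        out = Tensor(
            a.data**exponent,
            _parents=(a,),
            _backward=lambda g: ((a, g * exponent * a.data ** (exponent - 1)),),
        )
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g: Array):
            if b.data.ndim == 1:
                ga = np.expand_dims(g, -1) * b.data
                gb = (a.data.reshape(-1, a.data.shape[-1]).T @ g.reshape(-1)) if a.data.ndim > 1 else np.outer(a.data, g).sum(axis=-1)
            elif a.data.ndim == 1:
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.outer(a.data, g)
            else:
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.swapaxes(a.data, -1, -2) @ g
            return (
                (a, _unbroadcast(ga, a.shape)),
                (b, _unbroadcast(gb, b.shape)),
            )

        return Tensor(out_data, _parents=(a, b), _backward=backward)

    # -- elementwise ---------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor(out_data, _parents=(a,), _backward=lambda g: ((a, g * out_data),))

    def log(self):
        a = self
        return Tensor(np.log(a.data), _parents=(a,), _backward=lambda g: ((a, g / a.data),))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor(
            out_data, _parents=(a,), _backward=lambda g: ((a, g * (1.0 - out_data**2)),)
        )

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor(
            a.data * mask, _parents=(a,), _backward=lambda g: ((a, g * mask),)
        )

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
        return Tensor(
            out_data,
            _parents=(a,),
            _backward=lambda g: ((a, g * out_data * (1.0 - out_data)),),
        )

    def sqrt(self):
        return self**0.5

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: Array):
            if axis is None:
                ga = np.broadcast_to(g, a.shape)
            else:
                g_exp = g if keepdims else np.expand_dims(g, axis)
                ga = np.broadcast_to(g_exp, a.shape)
            return ((a, np.ascontiguousarray(ga)),)

        return Tensor(out_data, _parents=(a,), _backward=backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ---------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor(
            a.data.reshape(shape),
            _parents=(a,),
            _backward=lambda g: ((a, g.reshape(a.shape)),),
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inverse = np.argsort(axes)
        return Tensor(
            a.data.transpose(axes),
            _parents=(a,),
            _backward=lambda g: ((a, g.transpose(inverse)),),
        )

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return Tensor(
            np.swapaxes(a.data, ax1, ax2),
            _parents=(a,),
            _backward=lambda g: ((a, np.swapaxes(g, ax1, ax2)),),
        )

    def __getitem__(self, index):
        a = self

        def backward(g: Array):
            ga = np.zeros_like(a.data)
            np.add.at(ga, index, g)
            return ((a, ga),)

        return Tensor(a.data[index], _parents=(a,), _backward=backward)


# ---------------------------------------------------------------------------
# Functional helpers
# ---------------------------------------------------------------------------


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    parents = tuple(tensors)
    out_data = np.concatenate([t.data for t in parents], axis=axis)
    sizes = [t.shape[axis] for t in parents]
    offsets = np.cumsum([0] + sizes)

    def backward(g: Array):
        grads = []
        for t, start, stop in zip(parents, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(start, stop)
            grads.append((t, np.ascontiguousarray(g[tuple(idx)])))
        return tuple(grads)

    return Tensor(out_data, _parents=parents, _backward=backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    parents = tuple(tensors)
    out_data = np.stack([t.data for t in parents], axis=axis)

    def backward(g: Array):
        return tuple((t, np.take(g, i, axis=axis)) for i, t in enumerate(parents))

    return Tensor(out_data, _parents=parents, _backward=backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # max-shift is a constant w.r.t. differentiation (softmax shift invariance)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, targets: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Mean cross-entropy of integer ``targets`` under ``logits`` (..., C).

    ``mask`` (same shape as targets, 1 = include) restricts the average to a
    subset of positions.
    """
    logp = log_softmax(logits, axis=-1)
    targets = np.asarray(targets)
    gathered = logp[(*np.indices(targets.shape), targets)]
    if mask is None:
        return -gathered.mean()
    mask = np.asarray(mask, dtype=np.float64)
    denom = max(mask.sum(), 1.0)
    return -(gathered * Tensor(mask)).sum() * (1.0 / denom)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw scores (numerically stable form)."""
    t = Tensor(np.asarray(targets, dtype=np.float64))
    x = logits
    # max(x, 0) - x*t + log(1 + exp(-|x|)); sign/relu built from constants of x
    loss = x.relu() - x * t + (1.0 + (-(x * Tensor(np.sign(x.data)))).exp()).log()
    return loss.mean()


def mse(pred: Tensor, targets: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(targets, dtype=np.float64))
    return (diff * diff).mean()
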