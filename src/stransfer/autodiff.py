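"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the compute core under the encoder, classifier and discriminator:
a flat tape of :class:`Tensor` nodes holding float64 arrays, with exactly
the operations the model graphs need (broadcast arithmetic, matmul, ReLU,
sigmoid, exp/log, reductions, concatenation).  Gradients are accumulated
by a topological backward sweep from a scalar loss.

Every primitive's vector-Jacobian product is checked against central
finite differences in the test suite; keep new ops covered the same way.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "relu", "sigmoid"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node on the autodiff tape.

    Parameters with ``requires_grad=True`` accumulate ``.grad`` during
    :meth:`backward`; everything else participates in the forward pass
    only.  Data is always a float64 ndarray (scalars become 0-d arrays).
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g, out):
            return (g * e * self.data ** (e - 1.0),)

        return Tensor._from_op(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g, out):
            return (g * mask,)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def sigmoid(self):
        # numerically stable split by sign
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def backward(g, out):
            s = out.data
            return (g * s * (1.0 - s),)

        return Tensor._from_op(out_data, (self,), backward)

    def exp(self):
        def backward(g, out):
            return (g * out.data,)

        return Tensor._from_op(np.exp(self.data), (self,), backward)

    def log(self):
        def backward(g, out):
            return (g / self.data,)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo (safe-log clamp)."""
        mask = self.data > lo

        def backward(g, out):
            return (g * mask,)

        return Tensor._from_op(np.maximum(self.data, lo), (self,), backward)

    def sqrt(self):
        return self**0.5

    # -- reductions & shape ---------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver ------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep tapes must not hit the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:  # leaf parameter
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, pg in zip(node._prev, node._backward(g, node)):
                if p.requires_grad:
                    grads[id(p)] = grads[id(p)] + pg if id(p) in grads else pg


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along `axis`, splitting the gradient back."""
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, out):
        return tuple(
            np.take(g, range(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def gather_rows(t: Tensor, idx) -> Tensor:
    """Select rows by index; gradient scatter-adds back (repeats allowed)."""
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g, out):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        return (full,)

    return Tensor._from_op(t.data[idx], (t,), backward)


def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()
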