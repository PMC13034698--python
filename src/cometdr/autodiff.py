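"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the recurrent multimodal classifier needs:
affine maps, elementwise arithmetic, sigmoid/tanh nonlinearities, basic
slicing, concatenation, reductions, and a numerically stable binary
cross-entropy-with-logits loss.  Gradients flow to any :class:`Tensor`
created with ``requires_grad=True``, including *input* tensors — which is
what integrated-gradients attribution differentiates with respect to.

All data is float64.  The engine is deliberately eager and single-threaded:
given identical inputs and seeds, forward and backward passes are
bit-reproducible.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = ["Tensor", "concat", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer mixed ndarray-Tensor arithmetic to our reflected ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _node(cls, data, parents: Iterable["Tensor"], backward) -> "Tensor":
        parents = tuple(parents)
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return self._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._node(out_data, (self, other), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return (full,)

        return self._node(out_data, (self,), backward)

    # -- nonlinearities and reductions -----------------------------------

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return self._node(s, (self,), lambda g: (g * s * (1.0 - s),))

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        return self._node(t, (self,), lambda g: (g * (1.0 - t * t),))

    def sum(self) -> "Tensor":
        shape = self.data.shape
        return self._node(
            self.data.sum(), (self,), lambda g: (np.broadcast_to(g, shape).copy(),)
        )

    def mean(self) -> "Tensor":
        n = self.data.size
        shape = self.data.shape
        return self._node(
            self.data.mean(),
            (self,),
            lambda g: (np.broadcast_to(g / n, shape).copy(),),
        )

    # -- backward --------------------------------------------------------

    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` into every reachable leaf."""
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        # self may itself be a leaf
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(out_data, tensors, backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross entropy from raw logits, numerically stable.

    ``loss = mean(softplus(z) - y*z)`` with ``softplus(z) = log(1 + e^z)``
    computed as ``max(z, 0) + log1p(exp(-|z|))``.
    """
    y = np.asarray(targets, dtype=np.float64).reshape(logits.data.shape)
    z = logits.data
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                     np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
        return (g * (p - y) / n,)

    return Tensor._node(loss.mean(), (logits,), backward)
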