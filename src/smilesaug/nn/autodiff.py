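"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the operation that
produced it; :meth:`Tensor.backward` walks the graph in reverse
topological order accumulating gradients. Only the operations needed by
the sequence models are implemented (broadcast add/mul, matmul,
pointwise nonlinearities, indexing, a fused 1-D convolution and fused
losses). Gradients are verified against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph plumbing ------------------------------------------------

    @staticmethod
    def _lift(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    @staticmethod
    def _node(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        live = tuple(p for p in parents if p.requires_grad or p._parents)
        if live:
            out.requires_grad = True
            out._parents = live
            out._backward = backward
        return out

    @staticmethod
    def _accumulate(tensor: "Tensor", grad: np.ndarray) -> None:
        if tensor.grad is None:
            tensor.grad = np.zeros_like(tensor.data)
        tensor.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(grad):
            if self.requires_grad or self._parents:
                self._accumulate(self, _unbroadcast(grad, self.data.shape))
            if other.requires_grad or other._parents:
                self._accumulate(other, _unbroadcast(grad, other.data.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(grad):
            if self.requires_grad or self._parents:
                self._accumulate(self, _unbroadcast(grad * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                self._accumulate(other, _unbroadcast(grad * self.data, other.data.shape))

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        """Matrix product; the left operand may carry leading batch axes."""
        other = self._lift(other)
        a, b = self.data, other.data

        def backward(grad):
            if self.requires_grad or self._parents:
                self._accumulate(self, grad @ b.T)
            if other.requires_grad or other._parents:
                if a.ndim == 2:
                    self._accumulate(other, a.T @ grad)
                else:
                    axes = tuple(range(a.ndim - 1))
                    self._accumulate(other, np.tensordot(a, grad, axes=(axes, axes)))

        return self._node(a @ b, (self, other), backward)

    __matmul__ = matmul

    # -- shape ---------------------------------------------------------

    def __getitem__(self, index) -> "Tensor":
        def backward(grad):
            if self.requires_grad or self._parents:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                np.add.at(self.grad, index, grad)

        return self._node(self.data[index], (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        original = self.data.shape

        def backward(grad):
            self._accumulate(self, grad.reshape(original))

        return self._node(self.data.reshape(*shape), (self,), backward)

    def sum(self) -> "Tensor":
        def backward(grad):
            self._accumulate(self, np.full_like(self.data, float(grad)))

        return self._node(self.data.sum(), (self,), backward)

    def mean_axis(self, axis: int) -> "Tensor":
        """Arithmetic mean over one axis (used for pooling over time)."""
        n = self.data.shape[axis]

        def backward(grad):
            self._accumulate(self, np.repeat(np.expand_dims(grad / n, axis), n, axis))

        return self._node(self.data.mean(axis=axis), (self,), backward)

    # -- nonlinearities ------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(grad):
            self._accumulate(self, grad * mask)

        return self._node(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        value = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(grad):
            self._accumulate(self, grad * value * (1.0 - value))

        return self._node(value, (self,), backward)

    def tanh(self) -> "Tensor":
        value = np.tanh(self.data)

        def backward(grad):
            self._accumulate(self, grad * (1.0 - value * value))

        return self._node(value, (self,), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, padding: str = "same") -> Tensor:
    """1-D convolution over the time axis.

    ``x`` is (N, T, C_in), ``weight`` is (k, C_in, C_out). ``same``
    padding keeps T; ``valid`` yields T - k + 1 steps. Implemented as a
    sum of k shifted matrix products, which is fast for small kernels.
    """
    k = weight.data.shape[0]
    if padding == "same":
        left, right = (k - 1) // 2, k // 2
        xp = np.pad(x.data, ((0, 0), (left, right), (0, 0)))
    elif padding == "valid":
        left = 0
        xp = x.data
    else:
        raise ValueError(f"unknown padding {padding!r}")
    t_out = xp.shape[1] - k + 1
    out = np.tile(bias.data, (x.data.shape[0], t_out, 1))
    for j in range(k):
        out += xp[:, j : j + t_out, :] @ weight.data[j]

    def backward(grad):
        if bias.requires_grad or bias._parents:
            Tensor._accumulate(bias, grad.sum(axis=(0, 1)))
        if weight.requires_grad or weight._parents:
            gw = np.stack(
                [
                    np.tensordot(xp[:, j : j + t_out, :], grad, axes=([0, 1], [0, 1]))
                    for j in range(k)
                ]
            )
            Tensor._accumulate(weight, gw)
        if x.requires_grad or x._parents:
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, j : j + t_out, :] += grad @ weight.data[j].T
            gx = gxp[:, left : left + x.data.shape[1], :] if padding == "same" else gxp
            Tensor._accumulate(x, gx)

    return Tensor._node(out, (x, weight, bias), backward)


def mse_loss(pred: Tensor, target: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Mean squared error over entries where ``mask`` is true."""
    target = np.asarray(target, dtype=np.float64)
    mask = np.ones_like(target, dtype=bool) if mask is None else mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mse_loss: no observed targets under the mask")
    residual = np.where(mask, pred.data - target, 0.0)

    def backward(grad):
        Tensor._accumulate(pred, float(grad) * 2.0 * residual / n)

    return Tensor._node((residual**2).sum() / n, (pred,), backward)


def bce_with_logits_loss(
    logits: Tensor, target: np.ndarray, mask: np.ndarray | None = None
) -> Tensor:
    """Numerically stable binary cross-entropy on raw logits."""
    target = np.asarray(target, dtype=np.float64)
    mask = np.ones_like(target, dtype=bool) if mask is None else mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("bce_with_logits_loss: no observed targets under the mask")
    z = logits.data
    # log(1 + exp(-|z|)) + max(z, 0) - z*y, the standard stable form
    loss = np.where(mask, np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - z * target, 0.0)
    prob = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def backward(grad):
        Tensor._accumulate(logits, float(grad) * np.where(mask, prob - target, 0.0) / n)

    return Tensor._node(loss.sum() / n, (logits,), backward)
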