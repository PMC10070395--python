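"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The graph-transformer layers in :mod:`molhgt.model` need gradients of a
scalar loss with respect to a few hundred parameter matrices. This module
provides exactly the tensor operations those layers use — elementwise
arithmetic with broadcasting, matmul, reductions, pointwise nonlinearities,
concatenation, row gathering and segment sums — each with an analytic
backward rule. Data is kept in float64 throughout for reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "segment_sum", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(grad, out):
            return (_unbroadcast(grad, self.shape), _unbroadcast(grad, other.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda grad, out: (-grad,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(grad, out):
            return (
                _unbroadcast(grad * other.data, self.shape),
                _unbroadcast(grad * self.data, other.shape),
            )

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(grad, out):
            return (
                _unbroadcast(grad / other.data, self.shape),
                _unbroadcast(-grad * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        def backward(grad, out):
            return (grad * exponent * self.data ** (exponent - 1),)

        return Tensor._from_op(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(grad, out):
            return (grad @ other.data.T, self.data.T @ grad)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        return Tensor._from_op(self.data.T, (self,), lambda grad, out: (grad.T,))

    # -- shaping -------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old = self.shape
        return Tensor._from_op(
            self.data.reshape(*shape), (self,), lambda grad, out: (grad.reshape(old),)
        )

    def __getitem__(self, key):
        def backward(grad, out):
            full = np.zeros_like(self.data)
            np.add.at(full, key, grad)
            return (full,)

        return Tensor._from_op(self.data[key], (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(grad, out):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    # -- pointwise nonlinearities ---------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda grad, out: (grad * out.data,))

    def log(self) -> "Tensor":
        return Tensor._from_op(np.log(self.data), (self,), lambda grad, out: (grad / self.data,))

    def sigmoid(self) -> "Tensor":
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # numerically stable
        return Tensor._from_op(
            out_data, (self,), lambda grad, out: (grad * out.data * (1.0 - out.data),)
        )

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        return Tensor._from_op(
            out_data, (self,), lambda grad, out: (grad * (1.0 - out.data**2),)
        )

    def softplus(self) -> "Tensor":
        # log(1 + e^x) = max(x, 0) + log1p(e^{-|x|}), stable for large |x|
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return Tensor._from_op(out_data, (self,), lambda grad, out: (grad * sig,))

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda grad, out: (grad * mask,))

    # -- autodiff driver -------------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this scalar into every reachable tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad, out):
        return tuple(np.split(grad, splits, axis=axis))

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def gather_rows(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``t[index]`` with scatter-add backward."""
    index = np.asarray(index, dtype=np.intp)

    def backward(grad, out):
        full = np.zeros_like(t.data)
        np.add.at(full, index, grad)
        return (full,)

    return Tensor._from_op(t.data[index], (t,), backward)


def segment_sum(t: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given per-row segment ids."""
    segments = np.asarray(segments, dtype=np.intp)
    out_data = np.zeros((num_segments,) + t.data.shape[1:])
    np.add.at(out_data, segments, t.data)

    def backward(grad, out):
        return (grad[segments],)

    return Tensor._from_op(out_data, (t,), backward)
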