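"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the model needs: broadcast arithmetic,
matmul, reductions, concatenation, row gather/segment-sum (for message
passing), SiLU/sigmoid, and a fused binary-cross-entropy-with-logits loss.
Gradients are accumulated by a topological backward sweep; correctness is
pinned by a finite-difference property test.
"""

from __future__ import annotations

import numpy as np


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> np.ndarray:
        return self.data

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

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

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data ** 2, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._make(out_data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self) -> "Tensor":
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sigmoid(self) -> "Tensor":
        s = _stable_sigmoid(self.data)
        return self._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def silu(self) -> "Tensor":
        s = _stable_sigmoid(self.data)
        out_data = self.data * s

        def backward(g):
            return (g * (s + self.data * s * (1.0 - s)),)

        return self._make(out_data, (self,), backward)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        return self._make(t, (self,), lambda g: (g * (1.0 - t ** 2),))

    # -- structural ops -------------------------------------------------------
    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            return tuple(np.split(g, splits, axis=axis))

        out = Tensor(out_data)
        out.requires_grad = any(t.requires_grad for t in tensors)
        if out.requires_grad:
            out._prev = tuple(tensors)
            out._backward = backward
        return out

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        index = np.asarray(index, dtype=int)
        out_data = self.data[index]

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, index, g)
            return (grad,)

        return self._make(out_data, (self,), backward)

    def segment_sum(self, index: np.ndarray, num_segments: int) -> "Tensor":
        """Row-wise scatter-add: out[k] = sum over rows i with index[i] == k."""
        index = np.asarray(index, dtype=int)
        out_data = np.zeros((num_segments,) + self.data.shape[1:])
        np.add.at(out_data, index, self.data)
        return self._make(out_data, (self,), lambda g: (g[index],))

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        out_data = self.data[:, start:stop]

        def backward(g):
            grad = np.zeros_like(self.data)
            grad[:, start:stop] = g
            return (grad,)

        return self._make(out_data, (self,), backward)

    # -- losses ---------------------------------------------------------------
    def bce_with_logits(self, targets: np.ndarray, mask: np.ndarray | None = None) -> "Tensor":
        """Mean binary cross-entropy over unmasked entries; numerically stable
        softplus form with analytic gradient sigmoid(z) - y."""
        y = np.asarray(targets, dtype=np.float64)
        m = np.ones_like(y) if mask is None else np.asarray(mask, dtype=np.float64)
        n = m.sum()
        if n == 0:
            raise ValueError("bce_with_logits: all entries masked")
        z = self.data
        elem = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
        out_data = (elem * m).sum() / n

        def backward(g):
            s = _stable_sigmoid(z)
            return (g * (s - y) * m / n,)

        return self._make(out_data, (self,), backward)

    # -- backward sweep -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("called backward on a tensor without grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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

        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._prev, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g, dtype=float, copy=True)
                else:
                    parent.grad = parent.grad + g


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    t = Tensor(data, requires_grad=True)
    return t
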