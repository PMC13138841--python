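"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the gated-fusion network needs: affine maps,
layer normalization, GELU/ReLU, softmax, sigmoid, elementwise arithmetic,
clipping, reductions and concatenation. Gradients accumulate into ``.grad``
after calling :meth:`Tensor.backward` on a scalar.

Broadcasting is supported for elementwise ops; gradients are summed back to
the original shapes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep for long loops
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g):
            self._accumulate(g)
            other._accumulate(g)

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def bw(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data**2)

        return Tensor(out_data, parents=(self, other), backward=bw)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, parents=(self,), backward=bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=bw)

    __matmul__ = matmul

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ nonlinearities
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(out_data, parents=(self,), backward=bw)

    def gelu(self):
        # exact (erf) form; derivative = Phi(x) + x * phi(x)
        x = self.data
        cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        out_data = x * cdf

        def bw(g):
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
            self._accumulate(g * (cdf + x * pdf))

        return Tensor(out_data, parents=(self,), backward=bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside [lo, hi]."""
        inside = (self.data >= lo) & (self.data <= hi)
        out_data = np.clip(self.data, lo, hi)

        def bw(g):
            self._accumulate(g * inside)

        return Tensor(out_data, parents=(self,), backward=bw)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accumulate(out_data * (g - dot))

        return Tensor(out_data, parents=(self,), backward=bw)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then scale and shift.

        Composed from primitive ops so the gradient is exact by construction.
        """
        mu = self.mean(axis=-1, keepdims=True)
        centered = self - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv_std = (var + eps) ** -0.5
        return centered * inv_std * gamma + beta


def concat(tensors: list, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accumulate(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=bw)
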