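"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numeric core the package's classifiers are trained with. It
implements exactly the operations the models need — broadcast arithmetic,
batched matrix products, the usual nonlinearities, reductions, and shape
ops — with gradients accumulated by topological-order backpropagation.
All data is float64; gradient correctness is enforced by finite-difference
tests rather than by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "softmax", "no_grad", "grad_enabled"]

_GRAD_STACK = [True]


def grad_enabled() -> bool:
    return _GRAD_STACK[-1]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_STACK.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_STACK.pop()
        return False


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the shape of its source operand."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        if not grad_enabled():
            parents = ()
            requires_grad = False
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward_fn = None
        self._backward = backward

    @property
    def _backward(self):
        return self._backward_fn

    @_backward.setter
    def _backward(self, fn):
        # only keep the closure when a backward pass can reach this node;
        # otherwise it would pin the whole upstream graph in memory
        self._backward_fn = fn if (fn is not None and self.requires_grad) else None

    # ---- graph plumbing -------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, iter(self._parents))]
        seen.add(id(self))
        while stack:
            node, it = stack[-1]
            advanced = False
            for parent in it:
                if id(parent) not in seen:
                    seen.add(id(parent))
                    stack.append((parent, iter(parent._parents)))
                    advanced = True
                    break
            if not advanced:
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward_fn is not None and node.requires_grad:
                node._backward_fn()
        # the graph is one-shot: break the closure/parent reference cycles so
        # intermediate arrays are freed by refcount, not the cyclic collector
        for node in topo:
            node._backward_fn = None
            node._parents = ()

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward():
            if self.requires_grad:
                self._accumulate(_sum_to_shape(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(out.grad, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(-out.grad)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward():
            if self.requires_grad:
                self._accumulate(_sum_to_shape(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(out.grad * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward():
            if self.requires_grad:
                self._accumulate(_sum_to_shape(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _sum_to_shape(-out.grad * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def backward():
            if self.requires_grad:
                g = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                self._accumulate(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                g = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                other._accumulate(_sum_to_shape(g, other.data.shape))

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

        out._backward = backward
        return out

    # ---- nonlinearities -------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * out.data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        out._backward = backward
        return out

    def sqrt(self):
        return self**0.5

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * (self.data > 0.0))

        out._backward = backward
        return out

    def sigmoid(self):
        # numerically stable two-branch evaluation
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(s, parents=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * s * (1.0 - s))

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only where unclipped."""
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        mask = (self.data >= lo) & (self.data <= hi)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * mask)

        out._backward = backward
        return out

    # ---- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inverse = np.argsort(axes)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad.transpose(*inverse))

        out._backward = backward
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along ``axis``, max-shifted for stability.

    Implemented as one primitive with the exact Jacobian-vector backward
    s * (g - sum(g * s)) to avoid materialising intermediate arrays at the
    size of the attention matrix.
    """
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    np.exp(shifted, out=shifted)
    shifted /= shifted.sum(axis=axis, keepdims=True)
    s = shifted
    out = Tensor(s, parents=(x,))

    def backward():
        if x.requires_grad:
            g = out.grad
            x._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    out._backward = backward
    return out
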