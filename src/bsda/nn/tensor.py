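"""Minimal reverse-mode autodiff over numpy arrays.

Just enough machinery for small MLPs/CNNs trained on a CPU: broadcasting
binary ops, matmul, elementwise nonlinearities, reductions, reshapes,
concatenation, and a fused softmax cross-entropy. Gradients are accumulated
in float64 throughout so finite-difference checks are tight.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["Tensor", "as_tensor", "cat", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus a gradient and a closure that propagates it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- binary ops -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad, b.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(-grad)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad * a.data, b.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-grad * a.data / b.data**2, b.shape))

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(grad * e * a.data ** (e - 1.0))

        return Tensor._from_op(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(grad @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ grad)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- elementwise ----------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad, a=self, y=out_data):
            if a.requires_grad:
                a._accumulate(grad * y)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(grad / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(grad, a=self, y=out_data):
            if a.requires_grad:
                a._accumulate(grad * 0.5 / y)

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(grad, a=self, m=mask):
            if a.requires_grad:
                a._accumulate(grad * m)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def gelu(self):
        """Exact (erf-based) GELU."""
        x = self.data
        cdf = 0.5 * (1.0 + special.erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)

        def backward(grad, a=self, c=cdf, p=pdf):
            if a.requires_grad:
                a._accumulate(grad * (c + a.data * p))

        return Tensor._from_op(x * cdf, (self,), backward)

    # -- reductions / shape ---------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad, a=self):
            if not a.requires_grad:
                return
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(grad.reshape(old_shape))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or None

        def backward(grad, a=self):
            if a.requires_grad:
                if axes is None:
                    a._accumulate(grad.T)
                else:
                    a._accumulate(grad.transpose(np.argsort(axes)))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate along `axis`, splitting the gradient back to each input."""
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, parts=tensors, offs=offsets):
        for i, t in enumerate(parts):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(offs[i], offs[i + 1])
                t._accumulate(grad[tuple(sl)])

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) and integer labels.

    Fused for numerical stability: the backward pass is (softmax - onehot)/B.
    """
    labels = np.asarray(labels).reshape(-1)
    z = logits.data
    z_shift = z - z.max(axis=1, keepdims=True)
    log_probs = z_shift - np.log(np.exp(z_shift).sum(axis=1, keepdims=True))
    n = z.shape[0]
    loss = -log_probs[np.arange(n), labels].mean()
    probs = np.exp(log_probs)

    def backward(grad, a=logits, p=probs, y=labels):
        if a.requires_grad:
            g = p.copy()
            g[np.arange(n), y] -= 1.0
            a._accumulate(grad * g / n)

    return Tensor._from_op(loss, (logits,), backward)
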