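"""A compact reverse-mode automatic-differentiation engine on NumPy arrays.

The model stack in this package (windowed-attention visual encoder,
patch-Transformer acoustic encoder, bidirectional cross-modal attention,
contrastive and explanation losses, gradient-based saliency) needs first-order
gradients with respect to both parameters and intermediate activations.  This
module provides exactly that: a ``Tensor`` wrapping an ``ndarray`` plus the
vectorised primitives the model uses (broadcast arithmetic, matmul, reductions,
shape ops, strided convolution / transposed convolution, the usual
nonlinearities).  Gradients are retained on every node, which is what the
class-activation-mapping code relies on to read ``d logit / d feature-map``.

Only first-order differentiation is supported; higher-order saliency weights
(Grad-CAM++) are obtained through the exp-logit closed form, which needs first
derivatives only.
"""

from __future__ import annotations

import contextlib
import math

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "concat", "stack", "pad2d"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (evaluation / saliency-path replays)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev = _prev
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery ------------------------------------------------------
    def _make(self, data, prev, backward):
        if not _GRAD_ENABLED or not any(p.requires_grad for p in prev):
            return Tensor(data)
        out = Tensor(data, _prev=prev)
        out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        # out-of-place accumulation: incoming grads are never mutated, so the
        # first one can be stored by reference and later ones summed afresh
        if self.grad is None:
            self.grad = grad if grad.dtype == self.data.dtype \
                else grad.astype(self.data.dtype)
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort; recursion would overflow on deep graphs
        seen: set[int] = {id(self)}
        order: list[Tensor] = []
        stack2: list[tuple[Tensor, iter]] = [(self, iter(self._prev))]
        while stack2:
            node, it = stack2[-1]
            advanced = False
            for child in it:
                if id(child) not in seen:
                    seen.add(id(child))
                    stack2.append((child, iter(child._prev)))
                    advanced = True
                    break
            if not advanced:
                order.append(node)
                stack2.pop()
        self._accum(grad)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # scalars adopt the peer's dtype so float32 graphs stay float32
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0.0))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def gelu(self):
        # exact Gaussian-error-linear unit
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out_data = x * cdf

        def backward(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
                self._accum(g * (cdf + x * pdf))

        return self._make(out_data, (self,), backward)

    def abs(self):
        out_data = np.abs(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        return self._make(out_data, (self,), backward)

    def maximum(self, other):
        other = self._coerce(other)
        out_data = np.maximum(self.data, other.data)

        def backward(g):
            mask = self.data >= other.data
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * (~mask), other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_detached(self, axis=None, keepdims=False) -> np.ndarray:
        """Max of the raw values, outside the graph (softmax stabilisation)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(in_shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, axes):
        out_data = np.transpose(self.data, axes)
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)


def concat(tensors, axis=0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(np.asarray(t)) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return tensors[0]._make(out_data, tuple(tensors), backward)


def stack(tensors, axis=0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(np.asarray(t)) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return tensors[0]._make(out_data, tuple(tensors), backward)


def pad2d(x: Tensor, ph: int, pw: int) -> Tensor:
    """Zero-pad the last two axes of a (..., H, W) tensor."""
    pads = [(0, 0)] * (x.ndim - 2) + [(ph, ph), (pw, pw)]
    out_data = np.pad(x.data, pads)
    sl = tuple([slice(None)] * (x.ndim - 2) + [slice(ph, out_data.shape[-2] - ph),
                                               slice(pw, out_data.shape[-1] - pw)])

    def backward(g):
        if x.requires_grad:
            x._accum(g[sl])

    return x._make(out_data, (x,), backward)
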