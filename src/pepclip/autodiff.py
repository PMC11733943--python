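"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the tensor operations the encoders and losses need:
broadcasting arithmetic, matmul (including batched), reductions,
element-wise nonlinearities, stacking, gather and basic indexing.
Gradients are accumulated in float64; every op is deterministic.

Usage mirrors the familiar define-by-run style::

    x = Tensor(np.ones((2, 3)), requires_grad=True)
    y = (x * 2.0).sum()
    y.backward()
    x.grad  # -> array of 2.0
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "stack", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        return self._make(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def backward(g, out):
            a, b = self.data, other.data
            a2 = a if a.ndim > 1 else a[None, :]
            b2 = b if b.ndim > 1 else b[:, None]
            g2 = g
            if a.ndim == 1:
                g2 = np.expand_dims(g2, -2)
            if b.ndim == 1:
                g2 = np.expand_dims(g2, -1)
            if self.requires_grad:
                ga = g2 @ np.swapaxes(b2, -1, -2)
                if a.ndim == 1:
                    ga = _unbroadcast(ga, (1, a.shape[0])).reshape(a.shape)
                else:
                    ga = _unbroadcast(ga, a.shape)
                self._accum(ga)
            if other.requires_grad:
                gb = np.swapaxes(a2, -1, -2) @ g2
                if b.ndim == 1:
                    gb = _unbroadcast(gb, (b.shape[0], 1)).reshape(b.shape)
                else:
                    gb = _unbroadcast(gb, b.shape)
                other._accum(gb)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def backward(g, out):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def backward(g, out):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    def take_rows(self, index: np.ndarray):
        """Gather rows (embedding lookup); `index` is an integer array."""
        index = np.asarray(index)

        def backward(g, out):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, index.reshape(-1), g.reshape(-1, self.shape[-1]))
                self._accum(full)

        return self._make(self.data[index], (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g, out):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(ge, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- element-wise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * out.data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * (1.0 - out.data**2))

        return self._make(out_data, (self,), backward)

    def relu(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return self._make(np.maximum(self.data, 0.0), (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * out.data * (1.0 - out.data))

        return self._make(out_data, (self,), backward)

    def gelu(self):
        """Exact Gaussian-error-linear unit: x * Phi(x)."""
        x = self.data
        phi = 0.5 * (1.0 + _erf(x / np.sqrt(2.0)))
        out_data = x * phi

        def backward(g, out):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
                self._accum(g * (phi + x * pdf))

        return self._make(out_data, (self,), backward)

    # -- composite numerics ----------------------------------------------------

    def softmax(self, axis=-1):
        shift = self.data.max(axis=axis, keepdims=True)  # constant shift
        e = (self - Tensor(shift)).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis=-1, keepdims=False):
        shift = self.data.max(axis=axis, keepdims=True)
        s = (self - Tensor(shift)).exp().sum(axis=axis, keepdims=True).log() + Tensor(shift)
        return s if keepdims else s.reshape(*np.delete(np.array(s.shape), axis))

    # -- autograd driver --------------------------------------------------------

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad, node)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors of identical shape along a new axis."""
    datas = np.stack([t.data for t in tensors], axis=axis)
    parents = tuple(tensors)

    def backward(g, out):
        slices = np.moveaxis(g, axis, 0)
        for t, gt in zip(tensors, slices):
            if t.requires_grad:
                t._accum(gt)

    req = _grad_enabled and any(t.requires_grad for t in tensors)
    out = Tensor(datas, requires_grad=req)
    if req:
        out._parents = parents
        out._backward = backward
    return out
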