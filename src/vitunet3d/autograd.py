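"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps a
float64/float32 numpy array and remembers the operation that produced it.
Calling :meth:`Tensor.backward` walks the tape in reverse topological order
and accumulates gradients into every tensor created with
``requires_grad=True``.

Only the operations the segmentation model needs are provided (broadcasted
arithmetic, batched matmul, reshape/transpose/pad/slice, exp/log/erf,
reductions, integer gather).  Shapes are never implicitly promoted beyond
numpy broadcasting rules.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _special

__all__ = ["Tensor", "no_grad", "concat"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

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
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return (-g,)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def backward(g):
            return (g * e * self.data ** (e - 1.0),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.outer(g, b) if a.ndim > 1 else g * b
                gb = a.T @ g if a.ndim > 1 else a * g
            elif a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.outer(a, g)
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return Tensor._make(np.log(self.data), (self,), backward)

    def erf(self):
        def backward(g):
            return (g * (2.0 / np.sqrt(np.pi)) * np.exp(-self.data ** 2),)

        return Tensor._make(_special.erf(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where un-clamped."""
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            return (g * mask,)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            return (g.reshape(old),)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for np.pad."""
        pw = tuple(tuple(p) for p in pad_width)
        slices = tuple(
            slice(b, b + s) for (b, _), s in zip(pw, self.shape)
        )

        def backward(g):
            return (g[slices],)

        return Tensor._make(np.pad(self.data, pw), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape

        def backward(g):
            full = np.zeros(shape, dtype=g.dtype)
            full[idx] = g
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    def take0(self, indices: np.ndarray):
        """Gather rows along axis 0 with an integer index array."""
        idx = np.asarray(indices)
        out_data = self.data[idx]
        shape = self.shape

        def backward(g):
            full = np.zeros(shape, dtype=g.dtype)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    # -- composites ----------------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def gelu(self):
        return self * 0.5 * (1.0 + (self * (1.0 / np.sqrt(2.0))).erf())

    def layer_norm(self, eps: float = 1e-5):
        """Normalize over the last axis (affine handled by the caller)."""
        mu = self.mean(axis=-1, keepdims=True)
        xc = self - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + eps) ** -0.5

    # -- backprop ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:
                if t.grad is None:
                    t.grad = g.copy()
                else:
                    t.grad += g
                continue
            parent_grads = t._backward(g)
            for p, pg in zip(t._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if p._backward is None and not p._parents:
                    # leaf
                    if p.grad is None:
                        p.grad = pg.copy()
                    else:
                        p.grad += pg
                else:
                    if id(p) in grads:
                        grads[id(p)] += pg
                    else:
                        grads[id(p)] = pg.astype(np.float64, copy=True)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        outs = []
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            outs.append(g[tuple(sl)])
        return tuple(outs)

    return Tensor._make(out_data, tuple(tensors), backward)
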