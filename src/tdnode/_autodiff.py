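"""Minimal reverse-mode automatic differentiation on numpy arrays.

The modelling core of this package (recurrent encoders, attention, the
neural-ODE vector field and the discretize-then-optimize training loop)
needs gradients of scalar losses with respect to a few thousand weights.
This module provides exactly that: a small tape-based reverse-mode engine
over :class:`numpy.ndarray`, supporting the operations those networks use
(broadcast arithmetic, matmul, batched attention contractions, sigmoid/
tanh/SELU, softmax, slicing, concatenation and reductions).

It is intentionally small rather than general: no higher-order gradients,
no in-place mutation of tensors that require gradients, float64 throughout
(which keeps the batched-vs-unbatched invariance checks tight).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows"]

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __sub__(self, other):
        other = Tensor._lift(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))

        return Tensor._make(self.data - other.data, (self, other), backward)

    def __rsub__(self, other):
        return Tensor._lift(other) - self

    def __neg__(self):
        def backward(g, out):
            return (-g,)

        return Tensor._make(-self.data, (self,), backward)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def backward(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def backward(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, out):
            return (g * s * (1.0 - s),)

        return Tensor._make(s, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(g, out):
            return (g * (1.0 - t * t),)

        return Tensor._make(t, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g, out):
            return (g * e,)

        return Tensor._make(e, (self,), backward)

    def selu(self):
        x = self.data
        pos = x > 0
        e = _SELU_ALPHA * np.exp(np.minimum(x, 0.0))
        y = _SELU_SCALE * np.where(pos, x, e - _SELU_ALPHA)
        d = _SELU_SCALE * np.where(pos, 1.0, e)

        def backward(g, out):
            return (g * d,)

        return Tensor._make(y, (self,), backward)

    def sqrt(self):
        r = np.sqrt(self.data)

        def backward(g, out):
            return (g * 0.5 / r,)

        return Tensor._make(r, (self,), backward)

    # -- reductions / reshapes ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, out):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g, out):
            return (g.reshape(self.shape),)

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    @property
    def T(self):
        def backward(g, out):
            return (g.T,)

        return Tensor._make(self.data.T, (self,), backward)

    def __getitem__(self, idx):
        def backward(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), backward)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g, out):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return Tensor._make(s, (self,), backward)

    # -- batched attention contractions ---------------------------------------
    def bdot_qk(self, keys: "Tensor"):
        """scores[b, r] = sum_d self[b, d] * keys[b, r, d]."""
        keys = Tensor._lift(keys)
        scores = np.einsum("bd,brd->br", self.data, keys.data)

        def backward(g, out):
            dq = np.einsum("br,brd->bd", g, keys.data)
            dk = np.einsum("br,bd->brd", g, self.data)
            return (dq, dk)

        return Tensor._make(scores, (self, keys), backward)

    def bdot_av(self, values: "Tensor"):
        """out[b, d] = sum_r self[b, r] * values[b, r, d]."""
        values = Tensor._lift(values)
        mixed = np.einsum("br,brd->bd", self.data, values.data)

        def backward(g, out):
            da = np.einsum("bd,brd->br", g, values.data)
            dv = np.einsum("br,bd->brd", self.data, g)
            return (da, dv)

        return Tensor._make(mixed, (self, values), backward)

    def fold_rows(self, rows: int):
        """Reshape (B*rows, d) -> (B, rows, d)."""
        b = self.data.shape[0] // rows
        return self.reshape(b, rows, self.data.shape[1])

    # -- autodiff driver -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf (parameter or input marked requires_grad)
                node.grad = g.copy() if node.grad is None else node.grad + g
                continue
            for p, pg in zip(node._parents, node._backward(g, node)):
                if not p.requires_grad or pg is None:
                    continue
                key = id(p)
                grads[key] = pg if key not in grads else grads[key] + pg
        return self


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, out):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tensors, backward)


def stack_rows(tensors) -> Tensor:
    """Stack 1-D/row tensors into a new leading axis."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=0)

    def backward(g, out):
        return tuple(g[i] for i in range(len(tensors)))

    return Tensor._make(data, tensors, backward)
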