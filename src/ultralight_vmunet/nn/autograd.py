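"""Reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for every operation, a
closure that maps the output gradient to the gradients of the operands.
``Tensor.backward`` walks the recorded graph in reverse topological order and
accumulates gradients into ``.grad``.  The operation set is deliberately small:
the elementwise/linear-algebra primitives here plus the segmentation-specific
kernels in :mod:`ultralight_vmunet.nn.functional`.

Dtype is preserved by every op (float32 for trained modules, float64 in
finite-difference tests), and all computation is deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "as_tensor", "concat"]


def as_tensor(x, dtype=None):
    """Wrap ``x`` in a Tensor (no copy when it already is one)."""
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ meta
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def numpy(self):
        return self.data

    def item(self):
        return self.data.item()

    def __float__(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (scan over tokens)
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
        if self.grad is None:
            self.grad = np.asarray(grad, dtype=self.data.dtype)
        else:
            self.grad = self.grad + grad
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                g = np.asarray(g, dtype=parent.data.dtype)
                parent.grad = g if parent.grad is None else parent.grad + g

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        a, b = self, as_tensor(other)
        return make(a.data + b.data, (a, b),
                    lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))

    __radd__ = __add__

    def __neg__(self):
        a = self
        return make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, as_tensor(other)
        return make(a.data * b.data, (a, b),
                    lambda g: (_unbroadcast(g * b.data, a.shape),
                               _unbroadcast(g * a.data, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, as_tensor(other)
        return make(a.data / b.data, (a, b),
                    lambda g: (_unbroadcast(g / b.data, a.shape),
                               _unbroadcast(-g * a.data / (b.data ** 2), b.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        a = self
        return make(a.data ** p, (a,), lambda g: (g * p * a.data ** (p - 1),))

    def __matmul__(self, other):
        a, b = self, as_tensor(other)
        out = a.data @ b.data

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return make(out, (a, b), backward)

    # -------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return make(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return make(a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        a = self

        def backward(g):
            z = np.zeros_like(a.data)
            np.add.at(z, idx, g)
            return (z,)

        return make(a.data[idx], (a,), backward)

    def index_select(self, axis: int, idx):
        """Gather along ``axis`` with an integer index array (scatter-add backward)."""
        a = self
        idx = np.asarray(idx)

        def backward(g):
            z = np.zeros_like(a.data)
            sl = [slice(None)] * a.ndim
            sl[axis] = idx
            np.add.at(z, tuple(sl), g)
            return (z,)

        return make(np.take(a.data, idx, axis=axis), (a,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, a.shape).copy(),)

        return make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis: int, keepdims: bool = False):
        """Max along one axis; the gradient flows to the (first) argmax."""
        a = self
        idx = np.argmax(a.data, axis=axis)
        out = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            z = np.zeros_like(a.data)
            np.put_along_axis(z, np.expand_dims(idx, axis), g, axis=axis)
            return (z,)

        if not keepdims:
            out = np.squeeze(out, axis=axis)
        return make(out, (a,), backward)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        a = self
        out = np.exp(a.data)
        return make(out, (a,), lambda g: (g * out,))

    def log(self):
        a = self
        return make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sigmoid(self):
        a = self
        s = expit(a.data)
        return make(s, (a,), lambda g: (g * s * (1.0 - s),))

    def silu(self):
        a = self
        s = expit(a.data)
        return make(a.data * s, (a,),
                    lambda g: (g * (s + a.data * s * (1.0 - s)),))

    def relu(self):
        a = self
        mask = a.data > 0
        return make(np.where(mask, a.data, 0.0), (a,), lambda g: (g * mask,))

    def softplus(self):
        a = self
        out = np.logaddexp(0.0, a.data)
        return make(out, (a,), lambda g: (g * expit(a.data),))

    def clip(self, lo, hi):
        a = self
        mask = (a.data > lo) & (a.data < hi)
        return make(np.clip(a.data, lo, hi), (a,), lambda g: (g * mask,))


def make(data, parents, backward):
    """Build a graph node from op output ``data`` and a backward closure."""
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def concat(tensors, axis: int = 0):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return make(np.concatenate([t.data for t in tensors], axis=axis),
                tuple(tensors), backward)
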