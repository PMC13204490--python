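"""Minimal reverse-mode automatic differentiation over numpy arrays.

Single-threaded, float64, fully deterministic: the property the training code
relies on is that identical seeds give bit-identical parameter trajectories.
Only the operations the package's models need are implemented; convolutions
use explicit im2col/col2im with scatter-add backward passes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ------------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if pending:
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- basic properties ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accumulate(-g) if a.requires_grad else None)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data**exponent

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._make(out_data, (a,), bwd)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bwd)

    # -- elementwise nonlinearities -----------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(
            out_data, (a,), lambda g: a._accumulate(g * out_data) if a.requires_grad else None
        )

    def log(self):
        a = self
        return Tensor._make(
            np.log(a.data), (a,), lambda g: a._accumulate(g / a.data) if a.requires_grad else None
        )

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._make(
            out_data,
            (a,),
            lambda g: a._accumulate(g * (1.0 - out_data**2)) if a.requires_grad else None,
        )

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))
        return Tensor._make(
            out_data,
            (a,),
            lambda g: a._accumulate(g * out_data * (1.0 - out_data)) if a.requires_grad else None,
        )

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(
            a.data * mask, (a,), lambda g: a._accumulate(g * mask) if a.requires_grad else None
        )

    def softplus(self):
        a = self
        out_data = np.logaddexp(0.0, a.data)
        sig = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))
        return Tensor._make(
            out_data, (a,), lambda g: a._accumulate(g * sig) if a.requires_grad else None
        )

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            denom = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = a.data == out_data
        mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties evenly
        res = out_data if keepdims else out_data.squeeze(axis)

        def bwd(g):
            if not a.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accumulate(gg * mask)

        return Tensor._make(res, (a,), bwd)

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if a.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                a._accumulate(out_data * (g - dot))

        return Tensor._make(out_data, (a,), bwd)

    def logsumexp(self, axis: int = -1):
        a = self
        mx = a.data.max(axis=axis, keepdims=True)
        e = np.exp(a.data - mx)
        s = e.sum(axis=axis, keepdims=True)
        out_data = (np.log(s) + mx).squeeze(axis)
        soft = e / s

        def bwd(g):
            if a.requires_grad:
                a._accumulate(np.expand_dims(g, axis) * soft)

        return Tensor._make(out_data, (a,), bwd)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = a.data.shape
        return Tensor._make(
            a.data.reshape(shape),
            (a,),
            lambda g: a._accumulate(g.reshape(orig)) if a.requires_grad else None,
        )

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes),
            (a,),
            lambda g: a._accumulate(g.transpose(inv)) if a.requires_grad else None,
        )

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                keys = idx if isinstance(idx, tuple) else (idx,)
                if any(isinstance(k, (np.ndarray, list)) for k in keys):
                    np.add.at(full, idx, g)  # fancy indexing may repeat entries
                else:
                    full[idx] += g
                a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bwd)

    def pad2d(self, pad: int):
        """Zero-pad the last two axes symmetrically."""
        a = self
        if pad == 0:
            return a
        width = [(0, 0)] * (a.data.ndim - 2) + [(pad, pad), (pad, pad)]
        sl = tuple(
            [slice(None)] * (a.data.ndim - 2) + [slice(pad, -pad), slice(pad, -pad)]
        )
        return Tensor._make(
            np.pad(a.data, width),
            (a,),
            lambda g: a._accumulate(g[sl]) if a.requires_grad else None,
        )

    def repeat2d(self, factor: int):
        """Nearest-neighbour upsampling of the last two axes."""
        a = self
        out_data = a.data.repeat(factor, axis=-2).repeat(factor, axis=-1)

        def bwd(g):
            if not a.requires_grad:
                return
            s = g.shape
            gg = g.reshape(*s[:-2], s[-2] // factor, factor, s[-1] // factor, factor)
            a._accumulate(gg.sum(axis=(-3, -1)))

        return Tensor._make(out_data, (a,), bwd)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bwd)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), bwd)
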