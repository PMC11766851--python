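"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: :class:`Tensor` wraps an ``ndarray`` and records
the operations applied to it; :meth:`Tensor.backward` walks the tape in
reverse topological order and accumulates gradients.  Only the operations the
segmentation network needs are provided (dense linear algebra, stride-1 3D
convolution, the factor-2 transposed convolution, windowed softmax, and the
usual pointwise nonlinearities).  Shapes follow the broadcasting rules of
numpy; gradients of broadcast operands are summed back to the operand shape.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled", "concat"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], tuple] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], tuple]) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: volumes make recursion depth unsafe
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other
        return self._make(a.data + b.data, (a, b),
                          lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other
        return self._make(a.data * b.data, (a, b),
                          lambda g: (_unbroadcast(g * b.data, a.shape),
                                     _unbroadcast(g * a.data, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other
        return self._make(a.data / b.data, (a, b),
                          lambda g: (_unbroadcast(g / b.data, a.shape),
                                     _unbroadcast(-g * a.data / (b.data ** 2), b.shape)))

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)
        return self._make(a.data ** e, (a,),
                          lambda g: (g * e * a.data ** (e - 1),))

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def back(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return self._make(a.data @ b.data, (a, b), back)

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,),
                          lambda g: (g * out_data * (1.0 - out_data),))

    def leaky_relu(self, negative_slope: float = 0.01):
        a = self
        mask = a.data >= 0
        out_data = np.where(mask, a.data, negative_slope * a.data)
        return self._make(out_data, (a,),
                          lambda g: (np.where(mask, g, negative_slope * g),))

    def gelu(self):
        """Gaussian error linear unit, exact (erf) form."""
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return self._make(x * cdf, (a,), lambda g: (g * (cdf + x * pdf),))

    def softmax(self, axis: int = -1):
        x = self.data
        y = np.exp(x - x.max(axis=axis, keepdims=True))
        y /= y.sum(axis=axis, keepdims=True)
        return self._make(y, (self,),
                          lambda g: (y * (g - (g * y).sum(axis=axis, keepdims=True)),))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return self._make(self.data.reshape(shape), (a,),
                          lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return self._make(self.data.transpose(axes), (self,),
                          lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        a = self

        def back(g):
            ga = np.zeros(a.shape, dtype=g.dtype)
            np.add.at(ga, idx, g)
            return (ga,)

        return self._make(self.data[idx], (a,), back)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for :func:`numpy.pad`."""
        pw = tuple((int(l), int(r)) for l, r in pad_width)
        a = self
        sl = tuple(slice(l, l + s) for (l, _), s in zip(pw, a.shape))
        return self._make(np.pad(self.data, pw), (a,), lambda g: (g[sl],))

    def roll(self, shift, axis):
        shift = tuple(np.atleast_1d(shift).tolist())
        axis = tuple(np.atleast_1d(axis).tolist())
        neg = tuple(-s for s in shift)
        return self._make(np.roll(self.data, shift, axis), (self,),
                          lambda g: (np.roll(g, neg, axis),))

    # -- convolution ----------------------------------------------------------
    def conv3d(self, weight: "Tensor", bias: "Tensor | None" = None,
               padding: int = 1):
        """3D cross-correlation, stride 1.

        ``self``: (N, C, D, H, W); ``weight``: (O, C, k, k, k); output keeps
        the spatial extent when ``padding == (k - 1) / 2``.
        """
        x, w = self, weight
        k = w.shape[2]
        p = int(padding)
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
        view = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        out = np.einsum("ncdhwijk,ocijk->nodhw", view, w.data, optimize=True)
        if bias is not None:
            out = out + bias.data.reshape(1, -1, 1, 1, 1)

        def back(g):
            gx = gw = gb = None
            if x.requires_grad:
                q = k - 1 - p
                gp = np.pad(g, ((0, 0), (0, 0), (q, q), (q, q), (q, q))) if q else g
                gview = sliding_window_view(gp, (k, k, k), axis=(2, 3, 4))
                wf = w.data[:, :, ::-1, ::-1, ::-1]
                gx = np.einsum("nodhwijk,ocijk->ncdhw", gview, wf, optimize=True)
            if w.requires_grad:
                gw = np.einsum("ncdhwijk,nodhw->ocijk", view, g, optimize=True)
            if bias is not None and bias.requires_grad:
                gb = g.sum(axis=(0, 2, 3, 4))
            return gx, gw, gb

        parents = (x, w) if bias is None else (x, w, bias)
        return self._make(out, parents, back)

    def conv_transpose3d_x2(self, weight: "Tensor", bias: "Tensor | None" = None):
        """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling).

        ``self``: (N, C, D, H, W); ``weight``: (C, O, 2, 2, 2); output
        (N, O, 2D, 2H, 2W).  Kernel and stride match, so output blocks do not
        overlap and the operation is a per-voxel linear expansion.
        """
        x, w = self, weight
        n, c, d, h, wd = x.shape
        o = w.shape[1]
        out6 = np.einsum("nczyx,copqr->nozpyqxr", x.data, w.data, optimize=True)
        out = out6.reshape(n, o, 2 * d, 2 * h, 2 * wd)
        if bias is not None:
            out = out + bias.data.reshape(1, -1, 1, 1, 1)

        def back(g):
            g6 = g.reshape(n, o, d, 2, h, 2, wd, 2)
            gx = gw = gb = None
            if x.requires_grad:
                gx = np.einsum("nozpyqxr,copqr->nczyx", g6, w.data, optimize=True)
            if w.requires_grad:
                gw = np.einsum("nczyx,nozpyqxr->copqr", x.data, g6, optimize=True)
            if bias is not None and bias.requires_grad:
                gb = g.sum(axis=(0, 2, 3, 4))
            return gx, gw, gb

        parents = (x, w) if bias is None else (x, w, bias)
        return self._make(out, parents, back)


class Parameter(Tensor):
    """A trainable tensor (leaf of the tape)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, back)
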