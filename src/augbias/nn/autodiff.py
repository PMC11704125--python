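"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: enough operations to express
convolutional encoders, projection heads, and the SSRL objectives, with
broadcasting-aware gradients. Tensors wrap ``numpy.ndarray``; calling
:meth:`Tensor.backward` on a scalar walks the tape in reverse topological
order. Operations whose inputs all have ``requires_grad=False`` build no tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "relu", "exp", "log", "sqrt", "concat", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helper -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (
                _unbroadcast(ga, self.data.shape),
                _unbroadcast(gb, other.data.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.data.ndim))[::-1]
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    @property
    def T(self):
        return self.transpose()

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return (np.broadcast_to(gg, shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- graph walk ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=False)
                else:
                    parent.grad = parent.grad + g

    def zero_grad(self):
        self.grad = None


# -- elementwise functions ---------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._make(x.data * mask, (x,), lambda g: (g * mask,))


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)
    return Tensor._make(out_data, (x,), lambda g: (g * out_data,))


def log(x: Tensor) -> Tensor:
    return Tensor._make(np.log(x.data), (x,), lambda g: (g / x.data,))


def sqrt(x: Tensor) -> Tensor:
    out_data = np.sqrt(x.data)
    return Tensor._make(out_data, (x,), lambda g: (g * 0.5 / out_data,))


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused per-channel batch normalization over (N, H, W) with closed-form
    backward; returns (out, batch_mean, batch_var) with stats as plain arrays."""
    x = Tensor._coerce(x)
    axes = (0, 2, 3)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    var = ((x.data - mu) ** 2).mean(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xh = (x.data - mu) * inv_std
    out = xh * gamma.data + beta.data

    def backward(g):
        ggamma = (g * xh).sum(axis=axes, keepdims=True)
        gbeta = g.sum(axis=axes, keepdims=True)
        gxh = g * gamma.data
        gx = (inv_std / m) * (m * gxh - gxh.sum(axis=axes, keepdims=True)
                              - xh * (gxh * xh).sum(axis=axes, keepdims=True))
        return (gx, ggamma, gbeta)

    return Tensor._make(out, (x, gamma, beta), backward), mu, var


__all__.append("batchnorm2d")


# -- convolution -------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*kh*kw, OH*OW) view-copy plus output spatial dims."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
    )
    return np.ascontiguousarray(cols).reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad):
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    gx = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        hi = i + stride * oh
        for j in range(kw):
            wj = j + stride * ow
            gx[:, :, i:hi:stride, j:wj:stride] += cols[:, :, i, j]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation, x:(N,C,H,W) w:(O,C,kh,kw) b:(O,)."""
    x = Tensor._coerce(x)
    o, c, kh, kw = w.data.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    w2 = w.data.reshape(o, c * kh * kw)
    out = np.matmul(w2, cols)  # (N, O, OH*OW)
    n = x.data.shape[0]
    out = out.reshape(n, o, oh, ow)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)

    x_shape = x.data.shape
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2 = np.ascontiguousarray(g.reshape(n, o, oh * ow))
        gw = np.tensordot(g2, cols, axes=([0, 2], [0, 2])).reshape(w.data.shape)
        gcols = np.matmul(w2.T, g2)  # (N, C*kh*kw, L)
        gx = _col2im(gcols, x_shape, kh, kw, stride, pad)
        if b is None:
            return (gx, gw)
        gb = g.sum(axis=(0, 2, 3))
        return (gx, gw, gb)

    return Tensor._make(out, parents, backward)
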