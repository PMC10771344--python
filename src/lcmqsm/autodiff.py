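"""Reverse-mode automatic differentiation on numpy arrays.

This is the compute core of the network: a minimal define-by-run tape
with exactly the operators the architecture needs — broadcast
arithmetic, matrix/vector products, same-padding 3-D convolution
(numba-compiled kernels), 2x average pooling, symmetric padding,
fixed-stencil filtering and leaky rectification. Gradients are accumulated by topological
traversal of the tape; every operator's adjoint is exercised against
central finite differences in the test suite.

Convolution layout: feature maps are (channels, x, y, z); kernel
weights are (out_channels, in_channels, kx, ky, kz) with odd spatial
size and zero same-padding.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.signal import fftconvolve


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (adjoint of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ---------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, grad):
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    # -- reductions / shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def sqrt(x: Tensor) -> Tensor:
    return x**0.5


def leaky_relu(x: Tensor, negative_slope: float = 0.1) -> Tensor:
    mask = np.where(x.data >= 0, 1.0, negative_slope)
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bwd
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """y = W x (+ b) for a vector x of shape (in,) and W of shape (out, in)."""
    y = w.data @ x.data
    if b is not None:
        y = y + b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(w.data.T @ g)
        if w.requires_grad:
            w._accumulate(np.outer(g, x.data))
        if b is not None and b.requires_grad:
            b._accumulate(g)

    out._backward = bwd
    return out


# -- 3-D convolution (same zero padding, stride 1) --------------------------


@njit(cache=True, fastmath=True)
def _conv3d_fwd(xp, w, X, Y, Z):
    C_out, C_in, kx, ky, kz = w.shape
    y = np.zeros((C_out, X, Y, Z))
    for o in range(C_out):
        for c in range(C_in):
            for a in range(kx):
                for b in range(ky):
                    for d in range(kz):
                        wv = w[o, c, a, b, d]
                        if wv == 0.0:
                            continue
                        for i in range(X):
                            for j in range(Y):
                                for l in range(Z):
                                    y[o, i, j, l] += wv * xp[c, i + a, j + b, d + l]
    return y


@njit(cache=True, fastmath=True)
def _conv3d_grad_w(xp, g, kx, ky, kz):
    C_out, C_in = g.shape[0], xp.shape[0]
    X, Y, Z = g.shape[1], g.shape[2], g.shape[3]
    gw = np.zeros((C_out, C_in, kx, ky, kz))
    for o in range(C_out):
        for c in range(C_in):
            for a in range(kx):
                for b in range(ky):
                    for d in range(kz):
                        s = 0.0
                        for i in range(X):
                            for j in range(Y):
                                for l in range(Z):
                                    s += g[o, i, j, l] * xp[c, i + a, j + b, d + l]
                        gw[o, c, a, b, d] = s
    return gw


@njit(cache=True, fastmath=True)
def _conv3d_grad_x(g, w, Xp, Yp, Zp):
    C_out, C_in, kx, ky, kz = w.shape
    X, Y, Z = g.shape[1], g.shape[2], g.shape[3]
    gxp = np.zeros((C_in, Xp, Yp, Zp))
    for o in range(C_out):
        for c in range(C_in):
            for a in range(kx):
                for b in range(ky):
                    for d in range(kz):
                        wv = w[o, c, a, b, d]
                        if wv == 0.0:
                            continue
                        for i in range(X):
                            for j in range(Y):
                                for l in range(Z):
                                    gxp[c, i + a, j + b, d + l] += wv * g[o, i, j, l]
    return gxp


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 3-D convolution (cross-correlation form)."""
    C_out, C_in, kx, ky, kz = w.data.shape
    if x.data.shape[0] != C_in:
        raise ValueError(
            f"conv3d: input has {x.data.shape[0]} channels, weights expect {C_in}"
        )
    _, X, Y, Z = x.data.shape
    px, py, pz = kx // 2, ky // 2, kz // 2
    xp = np.pad(x.data, ((0, 0), (px, px), (py, py), (pz, pz)))
    y = _conv3d_fwd(xp, w.data, X, Y, Z)
    if b is not None:
        y = y + b.data[:, None, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def bwd(g):
        g = np.ascontiguousarray(g)
        if w.requires_grad:
            w._accumulate(_conv3d_grad_w(xp, g, kx, ky, kz))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))
        if x.requires_grad:
            gxp = _conv3d_grad_x(g, w.data, *xp.shape[1:])
            x._accumulate(gxp[:, px : px + X, py : py + Y, pz : pz + Z])

    out._backward = bwd
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2x average pooling over the three spatial axes of (C, X, Y, Z)."""
    C, X, Y, Z = x.data.shape
    if X % 2 or Y % 2 or Z % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {(X, Y, Z)}")
    r = x.data.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2)
    out = Tensor(r.mean(axis=(2, 4, 6)), parents=(x,))

    def bwd(g):
        ge = np.broadcast_to(
            g[:, :, None, :, None, :, None] / 8.0, (C, X // 2, 2, Y // 2, 2, Z // 2, 2)
        )
        x._accumulate(ge.reshape(C, X, Y, Z))

    out._backward = bwd
    return out


def pad_symmetric(x: Tensor, pad: int) -> Tensor:
    """Symmetric (half-sample reflect) padding of a 3-D volume."""
    idx = [np.pad(np.arange(n), pad, mode="symmetric") for n in x.data.shape]
    mesh = np.ix_(*idx)
    out = Tensor(x.data[mesh], parents=(x,))

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, mesh, g)
        x._accumulate(gx)

    out._backward = bwd
    return out


def correlate_valid(x: Tensor, stencil: np.ndarray) -> Tensor:
    """Valid-mode correlation of a 3-D volume with a fixed (constant) stencil."""
    flipped = stencil[::-1, ::-1, ::-1]
    out = Tensor(fftconvolve(x.data, flipped, mode="valid"), parents=(x,))
    out._backward = lambda g: x._accumulate(fftconvolve(g, stencil, mode="full"))
    return out


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=float), requires_grad=True)
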