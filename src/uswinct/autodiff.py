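"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``backward()`` runs the chain rule through the recorded graph.  The op set is
exactly what the restoration network needs — broadcast arithmetic, batched
matmul, reshape/transpose/slice/concat/roll, 2-D convolution via im2col,
nearest-neighbour upsampling, softmax, GELU/ReLU and an index-gather for the
relative position bias table — plus an Adam optimizer.

Everything is float64 CPU NumPy; the engine favours correctness (it is
validated against finite differences in the test suite) over speed, which is
adequate at the image sizes this package trains on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "Adam", "concat", "conv2d", "upsample2x", "take", "softmax"]


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient back to the shape of the broadcast input."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (a, b) in enumerate(zip(g.shape, shape)) if b == 1 and a != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ------------------------------------------------
    @staticmethod
    def _from_op(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- shape ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._from_op(
            self.data.reshape(shape), (self,), lambda g: self._accum(g.reshape(old))
        )

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._from_op(
            self.data.transpose(axes), (self,), lambda g: self._accum(g.transpose(inv))
        )

    def __getitem__(self, idx) -> "Tensor":
        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor._from_op(self.data[idx], (self,), bw)

    def roll(self, shifts, axes) -> "Tensor":
        neg = tuple(-s for s in shifts)
        return Tensor._from_op(
            np.roll(self.data, shifts, axis=axes),
            (self,),
            lambda g: self._accum(np.roll(g, neg, axis=axes)),
        )

    def pad2d(self, ph: int, pw: int) -> "Tensor":
        """Zero-pad the trailing two axes symmetrically-ish: (0,ph) and (0,pw)."""
        width = [(0, 0)] * (self.ndim - 2) + [(0, ph), (0, pw)]
        H, W = self.data.shape[-2:]

        def bw(g):
            self._accum(g[..., :H, :W])

        return Tensor._from_op(np.pad(self.data, width), (self,), bw)

    # -- arithmetic ------------------------------------------------------
    def _binary(self, other, fwd, bw_self, bw_other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = fwd(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(bw_self(g, self.data, other.data), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(bw_other(g, self.data, other.data), other.data.shape))

        return Tensor._from_op(data, (self, other), bw)

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        return self._binary(
            other, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(
            other,
            lambda a, b: a / b,
            lambda g, a, b: g / b,
            lambda g, a, b: -g * a / b**2,
        )

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p: float):
        data = self.data**p
        return Tensor._from_op(
            data, (self,), lambda g: self._accum(g * p * self.data ** (p - 1))
        )

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._from_op(data, (self, other), bw)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._from_op(data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g: self._accum(g * mask))

    def gelu(self) -> "Tensor":
        """Exact Gaussian-error-linear unit 0.5*x*(1+erf(x/sqrt(2)))."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
        return Tensor._from_op(x * cdf, (self,), lambda g: self._accum(g * (cdf + x * pdf)))

    def exp(self) -> "Tensor":
        data = np.exp(self.data)
        return Tensor._from_op(data, (self,), lambda g: self._accum(g * data))

    def sqrt(self) -> "Tensor":
        data = np.sqrt(self.data)
        return Tensor._from_op(data, (self,), lambda g: self._accum(g * 0.5 / data))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; rows sum to one along ``axis``."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        x._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return Tensor._from_op(s, (x,), bw)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._from_op(data, tuple(tensors), bw)


def take(table: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows of a parameter table by a fixed integer index array."""

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx, g)
        table._accum(full)

    return Tensor._from_op(table.data[idx], (table,), bw)


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, L) patch matrix."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    n, c, h, w = x_shape
    out = np.zeros((n, c, h, w))
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, i, j
            ]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), x (N,C,H,W), weight (O,C,k,k)."""
    o, c, k, _ = weight.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, ho, wo = _im2col(xp, k, stride)
    wmat = weight.data.reshape(o, c * k * k)
    out = np.einsum("ok,nkl->nol", wmat, cols, optimize=True)
    if bias is not None:
        out = out + bias.data[None, :, None]
    n = x.data.shape[0]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g2 = g.reshape(n, o, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accum(g2.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.einsum("nol,nkl->ok", g2, cols, optimize=True)
            weight._accum(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = np.einsum("ok,nol->nkl", wmat, g2, optimize=True)
            gxp = _col2im(gcols, xp.shape, k, stride, ho, wo)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    return Tensor._from_op(out.reshape(n, o, ho, wo), parents, bw)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of (N, C, H, W)."""
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        n, c, h2, w2 = g.shape
        x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._from_op(data, (x,), bw)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
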