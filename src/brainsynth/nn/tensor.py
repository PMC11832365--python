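"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps an ndarray,
records the operation that produced it, and ``backward()`` walks the graph
in reverse topological order accumulating gradients.  It supports exactly
the operations the generative models need — broadcast arithmetic,
matmul, convolutions (2D and 3D) via im2col, pooling, upsampling, softmax
and the usual pointwise nonlinearities.  Gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple["Tensor", ...] = ()

    # -- graph plumbing --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _node(self.data / other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad or other._prev:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = _node(self.data**p, (self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out

    # -- pointwise --------------------------------------------------------
    def exp(self):
        out = _node(np.exp(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        out = _node(np.sqrt(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / np.maximum(out.data, 1e-12))
        return out

    def tanh(self):
        out = _node(np.tanh(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        s = s.astype(x.dtype, copy=False)
        out = _node(s, (self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def relu(self):
        out = _node(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype, copy=False)
        out = _node(self.data * mask, (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp with straight-through gradient inside the bounds."""
        out = _node(np.clip(self.data, lo, hi), (self,))
        inside = (self.data > lo) & (self.data < hi)
        out._backward = lambda g: self._accumulate(g * inside)
        return out

    def abs(self):
        out = _node(np.abs(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def matmul(self, other: "Tensor"):
        other = _as_tensor(other)
        out = _node(np.matmul(self.data, other.data), (self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad or other._prev:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    __matmul__ = matmul

    def softmax(self, axis: int = -1):
        m = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(m)
        s = e / e.sum(axis=axis, keepdims=True)
        out = _node(s, (self,))

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference passes)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()


def _node(data: np.ndarray, prev: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED[-1]:
        out._prev = tuple(p for p in prev if p.requires_grad or p._prev)
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._prev:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolution via im2col (2D and 3D), nearest upsampling, average pooling
# ---------------------------------------------------------------------------

def convnd(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """N-dimensional convolution (cross-correlation).

    ``x``: (N, Cin, *spatial); ``w``: (Cout, Cin, *kernel); ``b``: (Cout,).
    Same stride/pad on every spatial axis.  Implemented as im2col (via a
    sliding-window view) + matmul; the input gradient scatters column
    gradients back with one strided add per kernel offset.
    """
    N, Cin = x.shape[:2]
    spatial = x.shape[2:]
    nd = len(spatial)
    kernel = w.shape[2:]
    Cout = w.shape[0]
    Ks = int(np.prod(kernel))
    if pad:
        width = [(0, 0), (0, 0)] + [(pad, pad)] * nd
        xp = np.ascontiguousarray(np.pad(x.data, width))
    else:
        xp = np.ascontiguousarray(x.data)
    pspatial = xp.shape[2:]
    P = int(np.prod(pspatial))
    out_spatial = tuple((pspatial[i] - kernel[i]) // stride + 1 for i in range(nd))

    def _off_slice(ks):
        off = np.unravel_index(ks, kernel)
        return (slice(None), slice(None)) + tuple(
            slice(off[i], off[i] + stride * out_spatial[i], stride) for i in range(nd)
        )

    # Stride 1: single GEMM over all kernel offsets — stack the per-offset
    # (Cout, Cin) weight slices, multiply the whole padded input once, then
    # accumulate shifted strided views (no input copies).  Stride > 1: the
    # stacked intermediate would be stride^nd times larger than needed, so
    # fall back to one small contraction per offset.
    xpf = xp.reshape(N, Cin, P)
    if stride == 1:
        w2 = np.ascontiguousarray(
            np.moveaxis(w.data.reshape(Cout, Cin, Ks), 2, 0)
        ).reshape(Ks * Cout, Cin)
        z = np.matmul(w2, xpf).reshape((N, Ks, Cout) + pspatial)
        out_data = np.zeros((N, Cout) + out_spatial, dtype=x.data.dtype)
        for ks in range(Ks):
            out_data += z[:, ks][_off_slice(ks)]
    else:
        out_data = np.zeros((N, Cout) + out_spatial, dtype=x.data.dtype)
        acc = None
        for ks in range(Ks):
            off = np.unravel_index(ks, kernel)
            xs = xp[_off_slice(ks)]  # (N, Cin, *out_spatial) strided view
            wk = w.data[(slice(None), slice(None)) + off]  # (Cout, Cin)
            t = np.tensordot(wk, xs, axes=([1], [1]))  # (Cout, N, *out_spatial)
            acc = t if acc is None else acc + t
        out_data = np.ascontiguousarray(np.moveaxis(acc, 0, 1))
    if b is not None:
        out_data += b.data.reshape((1, Cout) + (1,) * nd)
    out = _node(out_data, (x, w) + ((b,) if b is not None else ()))

    def bw(g):
        if b is not None and (b.requires_grad or b._prev):
            b._accumulate(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
        need_x = x.requires_grad or x._prev
        need_w = w.requires_grad or w._prev
        if not (need_x or need_w):
            return
        if stride == 1:
            dz = np.zeros((N, Ks, Cout) + pspatial, dtype=x.data.dtype)
            for ks in range(Ks):
                dz[:, ks][_off_slice(ks)] = g
            dzf = dz.reshape(N, Ks * Cout, P)
            if need_w:
                gw2 = np.tensordot(dzf, xpf, axes=([0, 2], [0, 2]))  # (Ks*Cout, Cin)
                gw = np.moveaxis(gw2.reshape(Ks, Cout, Cin), 0, 2).reshape(w.shape)
                w._accumulate(gw)
            if need_x:
                dxp = np.matmul(w2.T, dzf).reshape((N, Cin) + pspatial)
                if pad:
                    sl = (slice(None), slice(None)) + tuple(
                        slice(pad, -pad) for _ in range(nd)
                    )
                    dxp = dxp[sl]
                x._accumulate(dxp)
        else:
            sp = tuple(range(2, 2 + nd))
            gw = np.zeros_like(w.data) if need_w else None
            dxp = np.zeros((N, Cin) + pspatial, dtype=x.data.dtype) if need_x else None
            for ks in range(Ks):
                off = np.unravel_index(ks, kernel)
                sl = _off_slice(ks)
                if need_w:
                    gw[(slice(None), slice(None)) + off] = np.tensordot(
                        g, xp[sl], axes=([0] + list(sp), [0] + list(sp))
                    )
                if need_x:
                    wk = w.data[(slice(None), slice(None)) + off]
                    dxp[sl] += np.tensordot(wk, g, axes=([0], [1])).swapaxes(0, 1)
            if need_w:
                w._accumulate(gw)
            if need_x:
                if pad:
                    slp = (slice(None), slice(None)) + tuple(
                        slice(pad, -pad) for _ in range(nd)
                    )
                    dxp = dxp[slp]
                x._accumulate(dxp)

    out._backward = bw
    return out


def upsample_nearest(x: Tensor, scale: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of every spatial axis of (N, C, *spatial)."""
    nd = x.ndim - 2
    data = x.data
    for ax in range(2, 2 + nd):
        data = np.repeat(data, scale, axis=ax)
    out = _node(data, (x,))

    def bw(g):
        for ax in range(2, 2 + nd):
            s = g.shape
            g = g.reshape(s[:ax] + (s[ax] // scale, scale) + s[ax + 1:]).sum(axis=ax + 1)
        x._accumulate(g)

    out._backward = bw
    return out


def avg_pool(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping average pooling of every spatial axis."""
    nd = x.ndim - 2
    data = x.data
    for ax in range(2, 2 + nd):
        s = data.shape
        data = data.reshape(s[:ax] + (s[ax] // k, k) + s[ax + 1:]).mean(axis=ax + 1)
    out = _node(data, (x,))

    def bw(g):
        for ax in range(2, 2 + nd):
            g = np.repeat(g, k, axis=ax) / k
        x._accumulate(g)

    out._backward = bw
    return out
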