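"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` runs reverse-mode accumulation over the recorded
graph.  Only the primitives needed by the depth-to-pressure models live here:
broadcast arithmetic, (batched) matmul, strided/transposed convolution via
im2col, softmax, reductions, shape ops, bilinear resize and a handful of
pointwise nonlinearities.  Everything is float64 NumPy, so repeated runs with
the same seed are bit-identical.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "resize_bilinear",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction ------------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd driver ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** (-1.0)

    def __pow__(self, p: float):
        p = float(p)
        out = Tensor._make(self.data ** p, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = backward if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(np.matmul(self.data, other.data), (self, other), None)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(np.float64))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(np.float64))

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor._make(val, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * val)

        out._backward = backward if out.requires_grad else None
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward if out.requires_grad else None
        return out

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        val = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # numerically stable
        out = Tensor._make(val, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * val * (1.0 - val))

        out._backward = backward if out.requires_grad else None
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor._make(val, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - val * val))

        out._backward = backward if out.requires_grad else None
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = backward if out.requires_grad else None
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope)
        out = Tensor._make(self.data * scale, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * scale)

        out._backward = backward if out.requires_grad else None
        return out

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + _erf(x / math.sqrt(2.0)))
        out = Tensor._make(x * cdf, (self,), None)

        def backward(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
                self._accum(g * (cdf + x * pdf))

        out._backward = backward if out.requires_grad else None
        return out

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only inside the open interval."""
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor._make(np.clip(self.data, lo, hi), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = backward if out.requires_grad else None
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._make(s, (self,), None)

        def backward(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        out._backward = backward if out.requires_grad else None
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor._make(self.data.reshape(shape), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        out._backward = backward if out.requires_grad else None
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor._make(self.data.transpose(axes), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = backward if out.requires_grad else None
        return out

    @property
    def T(self):
        return self.transpose(*reversed(range(self.ndim)))

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = backward if out.requires_grad else None
        return out

    def flip(self, axes: tuple[int, ...]):
        out = Tensor._make(np.flip(self.data, axes), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(np.flip(g, axes))

        out._backward = backward if out.requires_grad else None
        return out

    def pad2d(self, pad_h: int, pad_w: int):
        """Zero-pad the two trailing (spatial) axes symmetrically."""
        if pad_h == 0 and pad_w == 0:
            return self
        spec = [(0, 0)] * (self.ndim - 2) + [(pad_h, pad_h), (pad_w, pad_w)]
        out = Tensor._make(np.pad(self.data, spec), (self,), None)
        sl = tuple([slice(None)] * (self.ndim - 2)
                   + [slice(pad_h, self.shape[-2] + pad_h),
                      slice(pad_w, self.shape[-1] + pad_w)])

        def backward(g):
            if self.requires_grad:
                self._accum(g[sl])

        out._backward = backward if out.requires_grad else None
        return out

    def dilate2d(self, stride_h: int, stride_w: int):
        """Insert ``stride-1`` zeros between entries of the spatial axes."""
        if stride_h == 1 and stride_w == 1:
            return self
        h, w = self.shape[-2], self.shape[-1]
        new = self.shape[:-2] + ((h - 1) * stride_h + 1, (w - 1) * stride_w + 1)
        data = np.zeros(new, dtype=np.float64)
        sl = tuple([slice(None)] * (self.ndim - 2)
                   + [slice(None, None, stride_h), slice(None, None, stride_w)])
        data[sl] = self.data
        out = Tensor._make(data, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g[sl])

        out._backward = backward if out.requires_grad else None
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, None)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = backward if out.requires_grad else None
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, Ho, Wo, C, kh, kw) view-based patch extraction."""
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,Ho*,Wo*,kh,kw
    win = win[:, :, ::sh, ::sw]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int | tuple[int, int] = 1,
           padding: int | tuple[int, int] = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, weight (O, C, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    n, c, h, width = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c} vs weight {c2}")
    xp = np.pad(x.data, [(0, 0), (0, 0), (ph, ph), (pw, pw)]) if (ph or pw) else x.data
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (width + 2 * pw - kw) // sw + 1
    cols = _im2col(xp, kh, kw, sh, sw).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(o, -1)
    val = (cols @ wmat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    if b is not None:
        val = val + b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(val, parents, None)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)).reshape(b.shape))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros((n, c, h + 2 * ph, width + 2 * pw))
            dc = dcols.transpose(0, 3, 4, 5, 1, 2)  # N,C,kh,kw,Ho,Wo
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho * sh:sh, j:j + wo * sw:sw] += dc[:, :, i, j]
            if ph or pw:
                dxp = dxp[:, :, ph:ph + h, pw:pw + width]
            x._accum(dxp)

    out._backward = backward if out.requires_grad else None
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int | tuple[int, int] = 1,
                     padding: int | tuple[int, int] = 0) -> Tensor:
    """Transposed convolution; weight layout (C_in, C_out, kh, kw).

    Output spatial size is ``(H - 1) * stride + k - 2 * padding``.  Realized
    as zero-insertion dilation followed by a stride-1 convolution with the
    spatially flipped, channel-swapped kernel, so gradients come for free.
    """
    x, w = as_tensor(x), as_tensor(w)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    kh, kw = w.shape[2], w.shape[3]
    xd = x.dilate2d(sh, sw)
    wf = w.flip((2, 3)).transpose(1, 0, 2, 3)
    return conv2d(xd, wf, b, stride=1, padding=(kh - 1 - ph, kw - 1 - pw))


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D linear-interpolation matrix mapping n_in samples to n_out."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    t = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(t).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = t - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Separable bilinear resize of the trailing two axes (endpoint-aligned)."""
    x = as_tensor(x)
    h, w = x.shape[-2], x.shape[-1]
    ho, wo = out_hw
    mh = _interp_matrix(h, ho)
    mw = _interp_matrix(w, wo)
    val = np.einsum("ij,...jk,lk->...il", mh, x.data, mw, optimize=True)
    out = Tensor._make(val, (x,), None)

    def backward(g):
        if x.requires_grad:
            x._accum(np.einsum("ji,...jk,kl->...il", mh, g, mw, optimize=True))

    out._backward = backward if out.requires_grad else None
    return out
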