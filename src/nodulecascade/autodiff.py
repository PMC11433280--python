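"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the nodule-cascade networks need:
broadcasting arithmetic, matmul, reductions, indexing/gather, concat,
(grouped / dilated / strided) 2-D convolution via im2col, block average
pooling and dense-matrix bilinear interpolation.  Gradients flow through a
dynamically recorded tape; ``backward`` runs a topological sweep.

The engine favours clarity and vectorised numpy over micro-optimisation;
at the patch sizes used here (<= 224 x 224, narrow channel widths) a full
forward/backward step is a few tens of milliseconds on one CPU core.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "concat",
    "conv2d",
    "avg_pool2d",
    "bilinear_resize",
    "no_grad",
    "is_grad_enabled",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
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
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"],
              backward: Callable[[np.ndarray], Sequence[np.ndarray | None]]) -> "Tensor":
        parents = tuple(parents)
        needs = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=needs)
        if needs:
            out._parents = parents
            out._backward = backward
        return out

    # -- basic introspection --------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                # retained on every grad-requiring node (leaves for the
                # optimiser, intermediates e.g. for Grad-CAM)
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
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
        o = astensor(other)
        return Tensor._make(self.data + o.data, (self, o),
                            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        o = astensor(other)
        return Tensor._make(self.data * o.data, (self, o),
                            lambda g: (_unbroadcast(g * o.data, self.shape),
                                       _unbroadcast(g * self.data, o.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = astensor(other)
        return Tensor._make(self.data / o.data, (self, o),
                            lambda g: (_unbroadcast(g / o.data, self.shape),
                                       _unbroadcast(-g * self.data / (o.data ** 2), o.shape)))

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._make(self.data ** e, (self,),
                            lambda g: (g * e * self.data ** (e - 1),))

    def __matmul__(self, other):
        o = astensor(other)
        return Tensor._make(self.data @ o.data, (self, o),
                            lambda g: (g @ o.data.swapaxes(-1, -2),
                                       self.data.swapaxes(-1, -2) @ g))

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: (g * e,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        r = np.sqrt(self.data)
        return Tensor._make(r, (self,), lambda g: (g / (2.0 * r),))

    def maximum(self, other):
        o = astensor(other)
        out = np.maximum(self.data, o.data)
        mask = self.data >= o.data
        return Tensor._make(out, (self, o),
                            lambda g: (_unbroadcast(g * mask, self.shape),
                                       _unbroadcast(g * (~mask), o.shape)))

    # -- reductions / reshaping -----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(out, (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        out = self.data[idx]

        def back(g):
            dx = np.zeros_like(self.data)
            np.add.at(dx, idx, g)
            return (dx,)

        return Tensor._make(np.array(out, copy=True), (self,), back)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tensors, back)


# ---------------------------------------------------------------------------
# Spatial operators (NCHW layout)
# ---------------------------------------------------------------------------

def _out_size(n: int, k: int, s: int, p: int, d: int) -> int:
    return (n + 2 * p - d * (k - 1) - 1) // s + 1


def _im2col(xp: np.ndarray, kh: int, kw: int, s: int, d: int,
            ho: int, wo: int) -> np.ndarray:
    """Padded input (N,C,Hp,Wp) -> patches (N,C,kh,kw,ho,wo)."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for a in range(kh):
        for b in range(kw):
            cols[:, :, a, b] = xp[:, :, a * d: a * d + ho * s: s,
                                  b * d: b * d + wo * s: s]
    return cols


def _col2im(dcols: np.ndarray, xshape: tuple, kh: int, kw: int,
            s: int, p: int, d: int) -> np.ndarray:
    """Adjoint of ``_im2col``: patches (N,C,kh,kw,ho,wo) -> (N,C,H,W)."""
    n, c, h, w = xshape
    ho, wo = dcols.shape[-2:]
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    for a in range(kh):
        for b in range(kw):
            dxp[:, :, a * d: a * d + ho * s: s,
                b * d: b * d + wo * s: s] += dcols[:, :, a, b]
    if p:
        return dxp[:, :, p:-p, p:-p]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation.

    x: (N, Cin, H, W); w: (Cout, Cin/groups, kh, kw); b: (Cout,) or None.
    ``groups == Cin`` with one output channel per group gives a depthwise
    convolution.
    """
    x, w = astensor(x), astensor(w)
    n, cin, h, wdt = x.shape
    cout, cin_g, kh, kw = w.shape
    if cin_g * groups != cin:
        raise ValueError(f"channel/group mismatch: {cin} in, {cin_g}x{groups}")
    cout_g = cout // groups
    ho = _out_size(h, kh, stride, padding, dilation)
    wo = _out_size(wdt, kw, stride, padding, dilation)
    if padding:
        xp = np.zeros((n, cin, h + 2 * padding, wdt + 2 * padding), x.data.dtype)
        xp[:, :, padding:padding + h, padding:padding + wdt] = x.data
    else:
        xp = x.data
    cols = _im2col(xp, kh, kw, stride, dilation, ho, wo)
    depthwise = groups == cin and cout == cin
    if groups == 1:
        colsf = cols.reshape(n, cin * kh * kw, ho * wo)
        wf = w.data.reshape(cout, cin * kh * kw)
        out = np.matmul(wf, colsf)  # (N, Cout, L) via batched sgemm
    elif depthwise:
        colsf = cols.reshape(n, cin, kh * kw, ho * wo)
        wf = w.data.reshape(cin, 1, kh * kw)
        out = np.matmul(wf, colsf).reshape(n, cin, ho * wo)
    else:
        colsf = cols.reshape(n, groups, cin_g * kh * kw, ho * wo)
        wf = w.data.reshape(groups, cout_g, cin_g * kh * kw)
        out = np.einsum("gok,ngkl->ngol", wf, colsf, optimize=True)
    out = np.ascontiguousarray(out.reshape(n, cout, ho, wo))
    if b is not None:
        b = astensor(b)
        out = out + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def back(g):
        if groups == 1:
            gf = g.reshape(n, cout, ho * wo)
            dw = np.tensordot(gf, colsf, axes=([0, 2], [0, 2])).reshape(w.shape)
            dcols = np.matmul(wf.T, gf)
        elif depthwise:
            gf = g.reshape(n, cin, 1, ho * wo)
            cg = cols.reshape(n, cin, kh * kw, ho * wo)
            dw = np.matmul(gf, cg.swapaxes(-1, -2)).sum(axis=0).reshape(w.shape)
            dcols = wf.swapaxes(-1, -2) @ gf
        else:
            gf = g.reshape(n, groups, cout_g, ho * wo)
            dw = np.einsum("ngol,ngkl->gok", gf, colsf, optimize=True).reshape(w.shape)
            dcols = np.einsum("gok,ngol->ngkl", wf, gf, optimize=True)
        dcols = dcols.reshape(n, cin, kh, kw, ho, wo)
        dx = _col2im(dcols, x.shape, kh, kw, stride, padding, dilation)
        if b is None:
            return dx, dw
        return dx, dw, g.sum(axis=(0, 2, 3))

    return Tensor._make(out, parents, back)


def avg_pool2d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping block mean (area down-sampling) by integer ``factor``."""
    x = astensor(x)
    n, c, h, w = x.shape
    if h % factor or w % factor:
        raise ValueError(f"spatial dims {h}x{w} not divisible by {factor}")
    ho, wo = h // factor, w // factor
    out = x.data.reshape(n, c, ho, factor, wo, factor).mean(axis=(3, 5))

    def back(g):
        gg = g[:, :, :, None, :, None] / (factor * factor)
        dx = np.broadcast_to(gg, (n, c, ho, factor, wo, factor))
        return (dx.reshape(n, c, h, w).copy(),)

    return Tensor._make(out, (x,), back)


def _interp_matrix(n_in: int, n_out: int, dtype=np.float32) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel centres)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = src - i0
    m[np.arange(n_out), i0] += 1.0 - frac
    m[np.arange(n_out), i1] += frac
    return m


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear spatial resize of an NCHW tensor via dense interp matrices."""
    x = astensor(x)
    n, c, h, w = x.shape
    ho, wo = out_hw
    mh = _interp_matrix(h, ho, x.data.dtype)
    mw = _interp_matrix(w, wo, x.data.dtype)
    out = np.einsum("oh,nchw,pw->ncop", mh, x.data, mw, optimize=True)

    def back(g):
        return (np.einsum("oh,ncop,pw->nchw", mh, g, mw, optimize=True),)

    return Tensor._make(out, (x,), back)
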