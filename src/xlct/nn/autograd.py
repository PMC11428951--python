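"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the volumetric encoder-decoder needs:
broadcast arithmetic, matmul, stride-1 3D convolution (vectorized numba
kernels for the forward, weight- and data-gradient passes), block max
pooling, zero-insertion upsampling (the transposed-convolution stride),
separable linear resampling, reductions, slicing and concatenation.  All
gradients are analytic and are exercised against finite differences in the
test suite.
"""

from __future__ import annotations

import numba
import numpy as np


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, pow_(other, -1.0)) if isinstance(other, Tensor) \
            else mul(self, 1.0 / other)

    def __rtruediv__(self, other):
        return mul(pow_(self, -1.0), other)

    def __pow__(self, p):
        return pow_(self, p)

    def __neg__(self):
        return mul(self, -1.0)

    def __getitem__(self, key):
        return getitem(self, key)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ----------------------------------------------------------------------------
# arithmetic
# ----------------------------------------------------------------------------

def add(a, b) -> Tensor:
    # python scalars stay scalars: wrapping them in 0-d float64 arrays would
    # silently promote float32 graphs
    if isinstance(b, (int, float)) and isinstance(a, Tensor):
        def backward_s(g):
            a._accumulate(g)

        return _node(a.data + b, (a,), backward_s)
    if isinstance(a, (int, float)) and isinstance(b, Tensor):
        return add(b, a)
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    if isinstance(b, (int, float)) and isinstance(a, Tensor):
        def backward_s(g):
            a._accumulate(g * b)

        return _node(a.data * b, (a,), backward_s)
    if isinstance(a, (int, float)) and isinstance(b, Tensor):
        return mul(b, a)
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), backward)


def pow_(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data**p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1))

    return _node(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    return pow_(a, 0.5)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _node(out_data, (a, b), backward)


# ----------------------------------------------------------------------------
# reductions, shaping
# ----------------------------------------------------------------------------

def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _node(out_data, (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum_(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return _node(out_data, (a,), backward)


def getitem(a, key) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[key]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[key] = g
            a._accumulate(full)

    return _node(out_data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _node(out_data, tuple(tensors), backward)


def amax(a, axis, keepdims=False) -> Tensor:
    """Max-reduction; gradient flows to the (first) argmax entries."""
    a = as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=True)
    mask = a.data == out_data
    # split ties evenly to keep the gradient well-defined
    mask = mask / mask.sum(axis=axis, keepdims=True)
    res = out_data if keepdims else np.squeeze(out_data, axis=axis)

    def backward(g):
        if a.requires_grad:
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accumulate(mask * gg)

    return _node(res, (a,), backward)


# ----------------------------------------------------------------------------
# nonlinearities
# ----------------------------------------------------------------------------

def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    return _node(out_data, (a,), backward)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    out_data = np.where(a.data > 0, a.data, slope * a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.where(a.data > 0, 1.0, slope))

    return _node(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    with np.errstate(over="ignore"):   # saturated tails flush to 0/1 exactly
        out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), backward)


# ----------------------------------------------------------------------------
# convolution and friends
# ----------------------------------------------------------------------------

@numba.njit(cache=True, fastmath=True)
def _conv3d_fwd_kernel(xp, w, out):  # pragma: no cover - jit
    # innermost loop runs over the contiguous output width (SIMD-friendly axpy)
    n_batch, c_in, _, _, _ = xp.shape
    c_out, _, kd, kh, kw = w.shape
    _, _, do, ho, wo = out.shape
    for n in range(n_batch):
        for o in range(c_out):
            for zd in range(do):
                for zh in range(ho):
                    acc = out[n, o, zd, zh]
                    acc[:] = 0.0
                    for c in range(c_in):
                        for a in range(kd):
                            for bb in range(kh):
                                row = xp[n, c, zd + a, zh + bb]
                                for e in range(kw):
                                    wv = w[o, c, a, bb, e]
                                    for zw in range(wo):
                                        acc[zw] += wv * row[zw + e]


@numba.njit(cache=True, fastmath=True)
def _conv3d_dw_kernel(xp, g, dw):  # pragma: no cover - jit
    n_batch, c_in, _, _, _ = xp.shape
    c_out, _, kd, kh, kw = dw.shape
    _, _, do, ho, wo = g.shape
    for n in range(n_batch):
        for zd in range(do):
            for zh in range(ho):
                for o in range(c_out):
                    grow = g[n, o, zd, zh]
                    for c in range(c_in):
                        for a in range(kd):
                            for bb in range(kh):
                                xrow = xp[n, c, zd + a, zh + bb]
                                for e in range(kw):
                                    s = 0.0
                                    for zw in range(wo):
                                        s += grow[zw] * xrow[zw + e]
                                    dw[o, c, a, bb, e] += s


def _corr3d(x: np.ndarray, w: np.ndarray, pad: tuple[int, int, int]) -> np.ndarray:
    """Raw stride-1 3D cross-correlation of x (N,C,D,H,W) with w (O,C,kd,kh,kw)."""
    pd, ph, pw = pad
    xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    kd, kh, kw = w.shape[2:]
    n, _, dp, hp, wp = xp.shape
    out = np.empty((n, w.shape[0], dp - kd + 1, hp - kh + 1, wp - kw + 1),
                   dtype=np.result_type(x.dtype, w.dtype))
    _conv3d_fwd_kernel(np.ascontiguousarray(xp),
                       np.ascontiguousarray(w.astype(out.dtype)), out)
    return out, xp


def conv3d(x, w, b=None, pad: int | tuple[int, int, int] = 1) -> Tensor:
    """Stride-1 3D convolution (cross-correlation) with symmetric zero padding."""
    x, w = as_tensor(x), as_tensor(w)
    pad = (pad, pad, pad) if isinstance(pad, int) else tuple(pad)
    out_data, xp = _corr3d(x.data, w.data, pad)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[None, :, None, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g = np.ascontiguousarray(g)
        if w.requires_grad:
            dw = np.zeros(w.shape, dtype=g.dtype)
            _conv3d_dw_kernel(np.ascontiguousarray(xp.astype(g.dtype)), g, dw)
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            kd, kh, kw = w.shape[2:]
            # adjoint of stride-1 correlation = correlation with the flipped
            # kernel at complementary padding
            wt = np.ascontiguousarray(
                np.flip(w.data, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4))
            dx, _ = _corr3d(g, wt,
                            tuple(k - 1 - p for k, p in zip((kd, kh, kw), pad)))
            x._accumulate(dx)

    return _node(out_data, parents, backward)


def maxpool3d(x, factors: tuple[int, int, int]) -> Tensor:
    """Non-overlapping block max pooling; block sizes must divide the dims."""
    x = as_tensor(x)
    n, c, d, h, w = x.shape
    fd, fh, fw = factors
    if d % fd or h % fh or w % fw:
        raise ValueError(f"pool factors {factors} do not divide {(d, h, w)}")
    xr = x.data.reshape(n, c, d // fd, fd, h // fh, fh, w // fw, fw)
    xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
        n, c, d // fd, h // fh, w // fw, fd * fh * fw)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gr = np.zeros(xr.shape, dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, d // fd, h // fh, w // fw, fd, fh, fw)
        gr = gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        x._accumulate(gr)

    return _node(out_data, (x,), backward)


def zero_insert(x, factors: tuple[int, int, int]) -> Tensor:
    """Upsample by inserting zeros (the interior stride of a transposed conv):
    output size = input size * factor along each spatial axis."""
    x = as_tensor(x)
    n, c, d, h, w = x.shape
    fd, fh, fw = factors
    out_data = np.zeros((n, c, d * fd, h * fh, w * fw), dtype=x.data.dtype)
    out_data[:, :, ::fd, ::fh, ::fw] = x.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g[:, :, ::fd, ::fh, ::fw])

    return _node(out_data, (x,), backward)


def interp_matrix(n_in: int, n_out: int, dtype=np.float64) -> np.ndarray:
    """1D linear-resampling matrix (n_out x n_in), cell-centred coordinates."""
    R = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        R[:, 0] = 1.0
        return R
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = src - i0
    R[np.arange(n_out), i0] += 1 - f
    R[np.arange(n_out), i1] += f
    return R


def axis_interp(x, R: np.ndarray, axis: int) -> Tensor:
    """Apply a fixed linear resampling matrix along one axis."""
    x = as_tensor(x)
    Rc = R.astype(x.data.dtype)

    def apply(mat, arr):
        moved = np.moveaxis(arr, axis, -1)
        return np.moveaxis(np.ascontiguousarray(moved) @ mat.T, -1, axis)

    out_data = apply(Rc, x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(apply(Rc.T, g))

    return _node(out_data, (x,), backward)


def resize_trilinear(x, out_dhw: tuple[int, int, int]) -> Tensor:
    """Separable linear resize of (N,C,D,H,W) to the given spatial shape."""
    x = as_tensor(x)
    for axis, n_out in zip((2, 3, 4), out_dhw):
        if x.shape[axis] != n_out:
            x = axis_interp(x, interp_matrix(x.shape[axis], n_out), axis)
    return x
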