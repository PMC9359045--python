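"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Implements exactly the operations the dose-prediction networks and the
differentiable DVH objective need: broadcast arithmetic, ReLU/sigmoid,
reductions, channel concatenation, 3D convolution (stride 1 or 2, 'same'
padding with ceil sizing), 2x max pooling, separable trilinear resampling,
and flat gathers. Tensors carry ``(channels, x, y, z)`` feature maps or
arbitrary ndarrays; there is no batch axis because training uses batch
size 1 throughout.

Gradients are accumulated by a topological backward sweep from the loss.
All backward closures are exact (verified against central finite
differences in the test-suite), which is what makes the sigmoid-DVH term a
trainable objective rather than just an evaluation metric.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv3d",
    "maxpool3d_2x",
    "resample_trilinear",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction of op results --------------------------------------
    @classmethod
    def _op(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
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
        self.grad = np.ones_like(self.data, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._op(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._op(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other._pow_const(-1.0)

    def _pow_const(self, p: float):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._op(a.data**p, (a,), backward)

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return self._pow_const(float(p))

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._op(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = _sigmoid(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return Tensor._op(out_data, (a,), backward)

    # -- reductions and reshaping ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gexp = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gexp, a.shape).copy())

        return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        orig = a.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(orig))

        return Tensor._op(a.data.reshape(*shape), (a,), backward)

    def gather_flat(self, idx: np.ndarray):
        """Pick elements of the flattened tensor at integer positions ``idx``."""
        a = self
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g):
            if a.requires_grad:
                buf = np.zeros(a.data.size, dtype=np.float64)
                np.add.at(buf, idx, g.ravel())
                a._accum(buf.reshape(a.shape))

        return Tensor._op(a.data.reshape(-1)[idx], (a,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out.astype(x.dtype, copy=False)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._op(np.concatenate(datas, axis=axis), tensors, backward)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """3D convolution over a (C, X, Y, Z) feature map.

    Cubic kernels only (1 or 3 wide), zero 'same' padding, output spatial
    extent ``ceil(n / stride)`` per axis. Implemented as one matmul per
    kernel offset on strided views, which keeps memory flat and leans on
    BLAS for the arithmetic.
    """
    c_out, c_in, k, k2, k3 = w.shape
    assert k == k2 == k3, "cubic kernels only"
    if x.shape[0] != c_in:
        raise ValueError(f"conv3d: expected {c_in} input channels, got {x.shape[0]}")
    pad = k // 2
    sp = x.shape[1:]
    out_sp = tuple(-(-n // stride) for n in sp)
    n_out = int(np.prod(out_sp))
    xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3) if pad else x.data
    w2 = w.data.reshape(c_out, c_in, k * k * k)
    acc = np.zeros((c_out, n_out), dtype=x.data.dtype)
    views = []
    for di in range(k):
        for dj in range(k):
            for dl in range(k):
                v = xp[
                    :,
                    di : di + stride * (out_sp[0] - 1) + 1 : stride,
                    dj : dj + stride * (out_sp[1] - 1) + 1 : stride,
                    dl : dl + stride * (out_sp[2] - 1) + 1 : stride,
                ]
                views.append((di, dj, dl, v))
                acc += w2[:, :, (di * k + dj) * k + dl] @ v.reshape(c_in, n_out)
    out_data = acc.reshape((c_out,) + out_sp)
    if b is not None:
        out_data = out_data + b.data.reshape(c_out, 1, 1, 1)

    def backward(g):
        g2 = g.reshape(c_out, n_out)
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=1))
        if w.requires_grad:
            gw = np.zeros_like(w.data, dtype=np.float64)
            for di, dj, dl, v in views:
                gw[:, :, di, dj, dl] = g2 @ v.reshape(c_in, n_out).T
            w._accum(gw)
        if x.requires_grad:
            gxp = np.zeros(
                (c_in,) + tuple(n + 2 * pad for n in sp), dtype=np.float64
            )
            for di, dj, dl, _ in views:
                gslice = (w.data[:, :, di, dj, dl].T @ g2).reshape((c_in,) + out_sp)
                gxp[
                    :,
                    di : di + stride * (out_sp[0] - 1) + 1 : stride,
                    dj : dj + stride * (out_sp[1] - 1) + 1 : stride,
                    dl : dl + stride * (out_sp[2] - 1) + 1 : stride,
                ] += gslice
            if pad:
                gxp = gxp[:, pad:-pad, pad:-pad, pad:-pad]
            x._accum(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._op(out_data, parents, backward)


def maxpool3d_2x(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2 and ceil sizing (odd axes padded)."""
    c = x.shape[0]
    sp = x.shape[1:]
    if min(sp) < 2:
        from .core import ShapeError

        raise ShapeError(f"cannot 2x-pool spatial shape {sp}")
    out_sp = tuple(-(-n // 2) for n in sp)
    pad_sp = tuple(2 * n for n in out_sp)
    xp = np.full((c,) + pad_sp, -np.inf, dtype=x.data.dtype)
    xp[:, : sp[0], : sp[1], : sp[2]] = x.data
    windows = (
        xp.reshape(c, out_sp[0], 2, out_sp[1], 2, out_sp[2], 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(c, *out_sp, 8)
    )
    arg = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gwin = np.zeros((c,) + out_sp + (8,), dtype=np.float64)
        np.put_along_axis(gwin, arg[..., None], g[..., None], axis=-1)
        gxp = (
            gwin.reshape(c, out_sp[0], out_sp[1], out_sp[2], 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape((c,) + pad_sp)
        )
        x._accum(gxp[:, : sp[0], : sp[1], : sp[2]])

    return Tensor._op(out_data, (x,), backward)


def _interp_axis(x: Tensor, axis: int, n_out: int) -> Tensor:
    """Linear resampling of one spatial axis (half-voxel aligned, clamped)."""
    n_in = x.shape[axis]
    if n_in == n_out:
        return x
    coords = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    coords = np.clip(coords, 0.0, n_in - 1.0)
    i0 = np.floor(coords).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = coords - i0
    w0 = 1.0 - w1
    sh = [1] * x.data.ndim
    sh[axis] = n_out
    w0b, w1b = w0.reshape(sh), w1.reshape(sh)
    out_data = np.take(x.data, i0, axis=axis) * w0b + np.take(x.data, i1, axis=axis) * w1b

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros(x.shape, dtype=np.float64)
        gmove = np.moveaxis(gx, axis, 0)
        gg = np.moveaxis(g, axis, 0)
        np.add.at(gmove, i0, gg * np.moveaxis(w0b, axis, 0))
        np.add.at(gmove, i1, gg * np.moveaxis(w1b, axis, 0))
        x._accum(gx)

    return Tensor._op(out_data, (x,), backward)


def resample_trilinear(x: Tensor, target_spatial: tuple[int, int, int]) -> Tensor:
    """Trilinear resampling of a (C, X, Y, Z) map to a target spatial shape."""
    out = x
    for ax, n_out in zip((1, 2, 3), target_spatial):
        out = _interp_axis(out, ax, n_out)
    return out
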