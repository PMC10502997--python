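"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operations the segmentation network needs:
elementwise arithmetic, reductions, reshaping, batched matrix products,
softmax, 3D (dilated, strided) convolution and separable linear resizing.
Gradients flow through a dynamically built tape; :meth:`Tensor.backward`
accumulates ``.grad`` on every reachable tensor with ``requires_grad``.

Dtype is preserved end to end, so float64 tensors can be used for
finite-difference gradient verification while the network itself runs in
float32.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
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

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this tensor, accumulating ``.grad``."""
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological order (graphs can be deep)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)
        out_data = a.data + b.data

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(out_data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)
        out_data = a.data * b.data

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(out_data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)
        out_data = a.data / b.data

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._make(out_data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * p * a.data ** (p - 1))

        return Tensor._make(out_data, (a,), bwd)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self
        out_data = np.log(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(out_data, (a,), bwd)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0
        out_data = np.where(mask, a.data, 0)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(out_data, (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bwd)

    def clip(self, lo: float, hi: float):
        """Clamp values; the gradient passes through the interior only."""
        a = self
        mask = (a.data > lo) & (a.data < hi)
        out_data = np.clip(a.data, lo, hi)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(out_data, (a,), bwd)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not a.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.shape).astype(a.dtype, copy=False))

        return Tensor._make(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.shape
        out_data = a.data.reshape(shape)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g.reshape(orig))

        return Tensor._make(out_data, (a,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))
        out_data = a.data.transpose(axes)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))

        return Tensor._make(out_data, (a,), bwd)

    def softmax(self, axis: int):
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        e = np.exp(a.data - m)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if a.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                a._accumulate(out_data * (g - dot))

        return Tensor._make(out_data, (a,), bwd)


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    ts = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, ts, bwd)


def bmm(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product ``a @ b`` with matching leading dimensions."""
    out_data = np.matmul(a.data, b.data)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(np.matmul(g, np.swapaxes(b.data, -1, -2)))
        if b.requires_grad:
            b._accumulate(np.matmul(np.swapaxes(a.data, -1, -2), g))

    return Tensor._make(out_data, (a, b), bwd)


# -- 3D convolution -----------------------------------------------------------

def conv_output_size(i: int, k: int, s: int, p: int, d: int) -> int:
    """Spatial output length of a dilated, strided, padded convolution.

    ``o = floor((i + 2p - k - (k-1)(d-1)) / s) + 1``
    """
    num = i + 2 * p - k - (k - 1) * (d - 1)
    if num < 0:
        raise ValueError(
            f"convolution does not fit: i={i}, k={k}, s={s}, p={p}, d={d}"
        )
    return num // s + 1


def effective_kernel(k: int, d: int) -> int:
    """Receptive extent of a dilated kernel: ``n = k + (k-1)(d-1)``."""
    return k + (k - 1) * (d - 1)


def _pad_zeros(xd: np.ndarray, pd: int, ph: int, pw: int) -> np.ndarray:
    if pd == 0 and ph == 0 and pw == 0:
        return xd
    B, C, D, H, W = xd.shape
    xp = np.zeros((B, C, D + 2 * pd, H + 2 * ph, W + 2 * pw), dtype=xd.dtype)
    xp[:, :, pd:pd + D, ph:ph + H, pw:pw + W] = xd
    return xp


def _im2col(xp: np.ndarray, kernel, stride, dilation, out_spatial
            ) -> np.ndarray:
    """(Cin*K, B*M) column matrix via one strided view + one copy."""
    B, Cin = xp.shape[:2]
    kd, kh, kw = kernel
    sd, sh, sw = stride
    dd, dh, dw = dilation
    Do, Ho, Wo = out_spatial
    sB, sC, sD, sH, sW = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(Cin, kd, kh, kw, B, Do, Ho, Wo),
        strides=(sC, sD * dd, sH * dh, sW * dw, sB, sD * sd, sH * sh, sW * sw),
        writeable=False)
    return np.ascontiguousarray(view).reshape(Cin * kd * kh * kw,
                                              B * Do * Ho * Wo)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None,
           stride: tuple[int, int, int], padding: tuple[int, int, int],
           dilation: tuple[int, int, int]) -> Tensor:
    """3D cross-correlation over a (B, C, D, H, W) tensor.

    Forward is one im2col + one GEMM; backward recomputes the column matrix
    (rather than caching it) to keep peak memory flat, then scatter-adds the
    input gradient through the 27 (or K) kernel-tap views.
    """
    xd, wd = x.data, w.data
    B, Cin, D, H, W = xd.shape
    Cout, Cin_w, kd, kh, kw = wd.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input has {Cin}, weight expects {Cin_w}")
    sd, sh, sw = stride
    pd, ph, pw = padding
    dd, dh, dw = dilation
    Do = conv_output_size(D, kd, sd, pd, dd)
    Ho = conv_output_size(H, kh, sh, ph, dh)
    Wo = conv_output_size(W, kw, sw, pw, dw)
    K = kd * kh * kw
    M = B * Do * Ho * Wo

    xp = _pad_zeros(xd, pd, ph, pw)
    col = _im2col(xp, (kd, kh, kw), stride, dilation, (Do, Ho, Wo))
    out2 = wd.reshape(Cout, Cin * K) @ col
    out_data = np.ascontiguousarray(
        out2.reshape(Cout, B, Do, Ho, Wo).transpose(1, 0, 2, 3, 4))
    if b is not None:
        out_data += b.data.reshape(1, Cout, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        g2 = np.ascontiguousarray(g.transpose(1, 0, 2, 3, 4)).reshape(Cout, M)
        if w.requires_grad:
            col_b = _im2col(_pad_zeros(xd, pd, ph, pw),
                            (kd, kh, kw), stride, dilation, (Do, Ho, Wo))
            w._accumulate((g2 @ col_b.T).reshape(wd.shape))
        if x.requires_grad:
            gcol = (wd.reshape(Cout, Cin * K).T @ g2).reshape(
                Cin, kd, kh, kw, B, Do, Ho, Wo)
            gxp = np.zeros_like(xp)
            for a in range(kd):
                for bb in range(kh):
                    for c in range(kw):
                        gxp[:, :,
                            a * dd: a * dd + (Do - 1) * sd + 1: sd,
                            bb * dh: bb * dh + (Ho - 1) * sh + 1: sh,
                            c * dw: c * dw + (Wo - 1) * sw + 1: sw
                            ] += gcol[:, a, bb, c].transpose(1, 0, 2, 3, 4)
            if pd or ph or pw:
                gxp = gxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W]
            x._accumulate(gxp)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._make(out_data, parents, bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               mean: np.ndarray, inv_std: np.ndarray) -> Tensor:
    """Per-channel affine normalization with a fused gradient.

    ``mean`` / ``inv_std`` are plain arrays of length C: either mini-batch
    statistics (training; their dependence on x is differentiated) or stored
    running statistics (eval; treated as constants). The caller signals the
    training case by passing ``batch_stats=True``-style semantics via
    :func:`batch_norm_train`.
    """
    C = x.shape[1]
    sh = (1, C, 1, 1, 1)
    xhat = (x.data - mean.reshape(sh)) * inv_std.reshape(sh)
    out_data = xhat * gamma.data.reshape(sh) + beta.data.reshape(sh)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3, 4)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            x._accumulate(g * (gamma.data.reshape(sh) * inv_std.reshape(sh)))

    return Tensor._make(out_data, (x, gamma, beta), bwd)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor,
                     eps: float) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Batch-statistics normalization; returns (out, batch_mean, batch_var).

    The gradient accounts for the dependence of the mini-batch mean and
    variance on x (standard fused batch-norm backward).
    """
    C = x.shape[1]
    sh = (1, C, 1, 1, 1)
    axes = (0, 2, 3, 4)
    n = x.data.size // C
    mu = x.data.mean(axis=axes)
    var = ((x.data - mu.reshape(sh)) ** 2).mean(axis=axes)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(sh)) * inv_std.reshape(sh)
    out_data = xhat * gamma.data.reshape(sh) + beta.data.reshape(sh)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data.reshape(sh)
            m1 = dxhat.mean(axis=axes).reshape(sh)
            m2 = (dxhat * xhat).mean(axis=axes).reshape(sh)
            x._accumulate(inv_std.reshape(sh) * (dxhat - m1 - xhat * m2))

    return Tensor._make(out_data, (x, gamma, beta), bwd), mu, var


# -- linear (trilinear) resizing ---------------------------------------------

def _linear_resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Dense (n_out, n_in) 1D linear-interpolation matrix, endpoint-aligned."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(src).astype(int)
    lo = np.minimum(lo, n_in - 2)
    frac = src - lo
    m[np.arange(n_out), lo] = 1.0 - frac
    m[np.arange(n_out), lo + 1] = frac
    return m


def resize_linear(x: Tensor, out_spatial: tuple[int, int, int]) -> Tensor:
    """Trilinear resize of the three trailing axes of a (B, C, D, H, W) tensor."""
    mats = [
        _linear_resize_matrix(x.shape[2 + i], out_spatial[i], x.dtype)
        for i in range(3)
    ]

    def apply(arr, transposed):
        for ax, m in zip((2, 3, 4), mats):
            mm = m if not transposed else m.T
            arr = np.moveaxis(np.matmul(np.moveaxis(arr, ax, -1), mm.T), -1, ax)
        return arr

    out_data = apply(x.data, transposed=False)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(apply(g, transposed=True))

    return Tensor._make(out_data, (x,), bwd)


def resize_nearest_labels(labels: np.ndarray, out_shape: tuple[int, ...]) -> np.ndarray:
    """Nearest-neighbor resize for integer label grids (not differentiable)."""
    out = labels
    for ax, n_out in enumerate(out_shape):
        n_in = out.shape[ax]
        if n_in == n_out:
            continue
        if n_in == 1:
            idx = np.zeros(n_out, dtype=int)
        else:
            idx = np.rint(np.linspace(0.0, n_in - 1.0, n_out)).astype(int)
        out = np.take(out, idx, axis=ax)
    return out
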