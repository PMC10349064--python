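"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small, dependency-free neural-network core sized for the desk-scale
models in this package: 1-D convolutional GANs on 2x512 signals and
cell-based 2-D CNNs on 40x40 recurrence images.  It provides a
:class:`Tensor` with a dynamically built computation graph, the layer
operations those models need (grouped/dilated conv1d/conv2d, batch
normalization, pooling, nearest-neighbour upsampling, phase shuffle),
losses, and SGD/Adam optimizers.

Everything is plain numpy executed single-threaded-deterministic:
identical inputs, parameters and seeds give bit-identical results, which
the reproducibility tests rely on.  Tensors default to float64 (used by
the finite-difference gradient checks); the training loops select
float32 through :class:`using_dtype` for speed.  Gradients of every op are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter", "SGD", "Adam", "no_grad", "using_dtype",
           "conv1d", "conv2d", "batch_norm", "linear",
           "max_pool2d", "avg_pool2d", "upsample1d_nearest", "pad1d",
           "phase_shuffle1d", "concat", "relu", "leaky_relu", "sigmoid",
           "tanh", "log", "clip", "softmax_cross_entropy",
           "bce_with_logits"]


_GRAD_ENABLED = True
_DTYPE = np.float64


class using_dtype:
    """Context manager selecting the array dtype for new tensors.

    float64 (the default) is used by the finite-difference gradient
    checks; the desk-scale training loops run under float32 for speed.
    """

    def __init__(self, dtype):
        self._dtype = np.dtype(dtype)

    def __enter__(self):
        global _DTYPE
        self._prev = _DTYPE
        _DTYPE = self._dtype
        return self

    def __exit__(self, *exc):
        global _DTYPE
        _DTYPE = self._prev
        return False


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """An array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = _GRAD_ENABLED and (
            requires_grad or any(p.requires_grad for p in parents))
        self._parents = parents if self.requires_grad else ()
        self._backward_fn = backward if self.requires_grad else None

    @property
    def _backward(self):
        return self._backward_fn

    @_backward.setter
    def _backward(self, fn) -> None:
        # dropping the closure when no gradient is required releases the
        # captured forward activations immediately (inference mode)
        self._backward_fn = fn if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph traversal ---------------------------------------------------

    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every graph leaf."""
        if grad is None:
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the graph as we go: closures capture forward
            # activations, and intermediate grads are no longer needed
            node._backward_fn = None
            node._parents = ()
            if not isinstance(node, Parameter) and node is not self:
                node.grad = None

    def _accum(self, g) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / other.data ** 2, other.data.shape))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(
            g, self.data.shape))
        return out

    def mean(self, axis=None, keepdims=False):
        out = Tensor(self.data.mean(axis=axis, keepdims=keepdims),
                     parents=(self,))
        denom = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape) / denom)
        out._backward = bw
        return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise nonlinearities

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: x._accum(g * (x.data > 0))
    return out


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    out = Tensor(np.where(x.data > 0, x.data, alpha * x.data), parents=(x,))
    out._backward = lambda g: x._accum(g * np.where(x.data > 0, 1.0, alpha))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x._accum(g * s * (1 - s))
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, parents=(x,))
    out._backward = lambda g: x._accum(g * (1 - t * t))
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: x._accum(g / x.data)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with pass-through gradient inside the interval."""
    out = Tensor(np.clip(x.data, lo, hi), parents=(x,))
    mask = (x.data >= lo) & (x.data <= hi)
    out._backward = lambda g: x._accum(g * mask)
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolutions

def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1, groups: int = 1) -> Tensor:
    """Grouped, dilated 1-D convolution.

    ``x``: (N, C, L); ``w``: (O, C/groups, K); output (N, O, L_out).
    Implemented as K shifted strided slices (no im2col materialization).
    """
    n, c, length = x.data.shape
    o, cg, k = w.data.shape
    k_eff = (k - 1) * dilation + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    l_out = (xp.shape[2] - k_eff) // stride + 1

    def tap(arr, j):
        start = j * dilation
        return arr[:, :, start:start + (l_out - 1) * stride + 1:stride]

    out_nlo = np.zeros((n, l_out, o))
    if groups == 1:
        for j in range(k):
            out_nlo += np.tensordot(tap(xp, j), w.data[:, :, j],
                                    axes=([1], [1]))
    elif groups == c and cg == 1 and o == c:
        out_nco = np.zeros((n, c, l_out))
        for j in range(k):
            out_nco += w.data[:, 0, j][None, :, None] * tap(xp, j)
        out_nlo = out_nco.transpose(0, 2, 1)
    else:
        og = o // groups
        for gi in range(groups):
            cs, os_ = slice(gi * cg, (gi + 1) * cg), slice(gi * og, (gi + 1) * og)
            for j in range(k):
                out_nlo[:, :, os_] += np.tensordot(
                    tap(xp, j)[:, cs], w.data[os_, :, j], axes=([1], [1]))
    out_d = np.ascontiguousarray(out_nlo.transpose(0, 2, 1))
    if b is not None:
        out_d += b.data.reshape(1, o, 1)
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_d, parents=parents)

    def bw(g):
        g_nlo = np.ascontiguousarray(g.transpose(0, 2, 1))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        dxp = np.zeros_like(xp) if x.requires_grad else None
        dw = np.zeros_like(w.data) if w.requires_grad else None
        if groups == 1:
            for j in range(k):
                xs = tap(xp, j)
                if dw is not None:
                    dw[:, :, j] = np.tensordot(g_nlo, xs,
                                               axes=([0, 1], [0, 2]))
                if dxp is not None:
                    tap(dxp, j)[...] += np.tensordot(
                        g_nlo, w.data[:, :, j], axes=([2], [0])
                    ).transpose(0, 2, 1)
        elif groups == c and cg == 1 and o == c:
            g_ncl = g
            for j in range(k):
                xs = tap(xp, j)
                if dw is not None:
                    dw[:, 0, j] = (g_ncl * xs).sum(axis=(0, 2))
                if dxp is not None:
                    tap(dxp, j)[...] += w.data[:, 0, j][None, :, None] * g_ncl
        else:
            og = o // groups
            for gi in range(groups):
                cs = slice(gi * cg, (gi + 1) * cg)
                os_ = slice(gi * og, (gi + 1) * og)
                for j in range(k):
                    xs = tap(xp, j)[:, cs]
                    if dw is not None:
                        dw[os_, :, j] = np.tensordot(
                            g_nlo[:, :, os_], xs, axes=([0, 1], [0, 2]))
                    if dxp is not None:
                        tap(dxp, j)[:, cs] += np.tensordot(
                            g_nlo[:, :, os_], w.data[os_, :, j],
                            axes=([2], [0])).transpose(0, 2, 1)
        if dw is not None:
            w._accum(dw)
        if dxp is not None:
            x._accum(dxp[:, :, padding:padding + length])
    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1, groups: int = 1) -> Tensor:
    """Grouped, dilated 2-D convolution with square kernels.

    ``x``: (N, C, H, W); ``w``: (O, C/groups, k, k); output (N, O, H', W').
    Implemented as k*k shifted strided slices.
    """
    n, c, h, wd = x.data.shape
    o, cg, kh, kw = w.data.shape
    kh_eff = (kh - 1) * dilation + 1
    kw_eff = (kw - 1) * dilation + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding)))
    ho = (xp.shape[2] - kh_eff) // stride + 1
    wo = (xp.shape[3] - kw_eff) // stride + 1

    def tap(arr, i, j):
        si, sj = i * dilation, j * dilation
        return arr[:, :,
                   si:si + (ho - 1) * stride + 1:stride,
                   sj:sj + (wo - 1) * stride + 1:stride]

    depthwise = groups == c and cg == 1 and o == c
    if depthwise:
        out_d = np.zeros((n, c, ho, wo))
        for i in range(kh):
            for j in range(kw):
                out_d += w.data[:, 0, i, j][None, :, None, None] * tap(xp, i, j)
    elif groups == 1:
        out_nhwo = np.zeros((n, ho, wo, o))
        for i in range(kh):
            for j in range(kw):
                out_nhwo += np.tensordot(tap(xp, i, j), w.data[:, :, i, j],
                                         axes=([1], [1]))
        out_d = np.ascontiguousarray(out_nhwo.transpose(0, 3, 1, 2))
    else:
        og = o // groups
        out_nhwo = np.zeros((n, ho, wo, o))
        for gi in range(groups):
            cs = slice(gi * cg, (gi + 1) * cg)
            os_ = slice(gi * og, (gi + 1) * og)
            for i in range(kh):
                for j in range(kw):
                    out_nhwo[..., os_] += np.tensordot(
                        tap(xp, i, j)[:, cs], w.data[os_, :, i, j],
                        axes=([1], [1]))
        out_d = np.ascontiguousarray(out_nhwo.transpose(0, 3, 1, 2))
    if b is not None:
        out_d += b.data.reshape(1, o, 1, 1)
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_d, parents=parents)

    def bw(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        dxp = np.zeros_like(xp) if x.requires_grad else None
        dw = np.zeros_like(w.data) if w.requires_grad else None
        if depthwise:
            for i in range(kh):
                for j in range(kw):
                    xs = tap(xp, i, j)
                    if dw is not None:
                        dw[:, 0, i, j] = (g * xs).sum(axis=(0, 2, 3))
                    if dxp is not None:
                        tap(dxp, i, j)[...] += \
                            w.data[:, 0, i, j][None, :, None, None] * g
        elif groups == 1:
            g_nhwo = np.ascontiguousarray(g.transpose(0, 2, 3, 1))
            for i in range(kh):
                for j in range(kw):
                    xs = tap(xp, i, j)
                    if dw is not None:
                        dw[:, :, i, j] = np.tensordot(
                            g_nhwo, xs, axes=([0, 1, 2], [0, 2, 3]))
                    if dxp is not None:
                        tap(dxp, i, j)[...] += np.tensordot(
                            g_nhwo, w.data[:, :, i, j], axes=([3], [0])
                        ).transpose(0, 3, 1, 2)
        else:
            og = o // groups
            g_nhwo = np.ascontiguousarray(g.transpose(0, 2, 3, 1))
            for gi in range(groups):
                cs = slice(gi * cg, (gi + 1) * cg)
                os_ = slice(gi * og, (gi + 1) * og)
                for i in range(kh):
                    for j in range(kw):
                        xs = tap(xp, i, j)[:, cs]
                        if dw is not None:
                            dw[os_, :, i, j] = np.tensordot(
                                g_nhwo[..., os_], xs,
                                axes=([0, 1, 2], [0, 2, 3]))
                        if dxp is not None:
                            tap(dxp, i, j)[:, cs] += np.tensordot(
                                g_nhwo[..., os_], w.data[os_, :, i, j],
                                axes=([3], [0])).transpose(0, 3, 1, 2)
        if dw is not None:
            w._accum(dw)
        if dxp is not None:
            x._accum(dxp[:, :, padding:padding + h, padding:padding + wd])
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# pooling / resampling

def _pool2d_prepare(x: Tensor, k: int, stride: int, padding: int,
                    fill: float):
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding)), constant_values=fill)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    return xp, win


def max_pool2d(x: Tensor, k: int = 3, stride: int = 1,
               padding: int = 1) -> Tensor:
    n, c, h, w = x.data.shape
    xp, win = _pool2d_prepare(x, k, stride, padding, -np.inf)
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], -1)[..., 0],
                 parents=(x,))

    def bw(g):
        hp, wp = xp.shape[2], xp.shape[3]
        # arg//k, arg%k are (n,c,ho,wo) offsets -> absolute padded indices;
        # scatter-add via bincount on flattened indices (much faster than
        # fancy-indexed np.add.at)
        oh = np.arange(ho)[:, None] * stride
        ow = np.arange(wo)[None, :] * stride
        abs_h = oh[None, None] + arg // k
        abs_w = ow[None, None] + arg % k
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        flat_idx = (((nn * c + cc) * hp + abs_h) * wp + abs_w).ravel()
        dxp = np.bincount(flat_idx, weights=g.ravel().astype(np.float64),
                          minlength=n * c * hp * wp)
        dxp = dxp.reshape(n, c, hp, wp).astype(g.dtype)
        x._accum(dxp[:, :, padding:padding + h, padding:padding + w])
    out._backward = bw
    return out


def avg_pool2d(x: Tensor, k: int = 3, stride: int = 1,
               padding: int = 1) -> Tensor:
    n, c, h, w = x.data.shape
    xp, win = _pool2d_prepare(x, k, stride, padding, 0.0)
    ho, wo = win.shape[2], win.shape[3]
    out = Tensor(win.mean(axis=(-2, -1)), parents=(x,))

    def bw(g):
        dxp = np.zeros(xp.shape, dtype=g.dtype)
        spread = g / (k * k)
        # accumulate per kernel offset on strided slices (no fancy indexing)
        for i in range(k):
            for j in range(k):
                dxp[:, :,
                    i:i + (ho - 1) * stride + 1:stride,
                    j:j + (wo - 1) * stride + 1:stride] += spread
        x._accum(dxp[:, :, padding:padding + h, padding:padding + w])
    out._backward = bw
    return out


def upsample1d_nearest(x: Tensor, factor: int = 2) -> Tensor:
    out = Tensor(np.repeat(x.data, factor, axis=2), parents=(x,))

    def bw(g):
        n, c, l = x.data.shape
        x._accum(g.reshape(n, c, l, factor).sum(axis=3))
    out._backward = bw
    return out


def pad1d(x: Tensor, left: int, right: int, value: float = 0.0) -> Tensor:
    out = Tensor(np.pad(x.data, ((0, 0), (0, 0), (left, right)),
                        constant_values=value), parents=(x,))

    def bw(g):
        x._accum(g[:, :, left:g.shape[2] - right])
    out._backward = bw
    return out


def phase_shuffle1d(x: Tensor, n_max: int, rng: np.random.Generator) -> Tensor:
    """Random per-feature-map temporal shift in [-n, n], reflection padded.

    Used in GAN discriminators so they cannot key on absolute phase.
    ``n_max = 0`` is the identity.
    """
    if n_max == 0:
        return x
    n, c, length = x.data.shape
    shifts = rng.integers(-n_max, n_max + 1, size=(n, c))
    base = np.arange(length)
    idx = base[None, None, :] - shifts[:, :, None]
    # reflect out-of-range indices back into [0, length)
    idx = np.abs(idx)
    idx = np.where(idx >= length, 2 * (length - 1) - idx, idx)
    out = Tensor(np.take_along_axis(x.data, idx, axis=2), parents=(x,))

    def bw(g):
        dx = np.zeros_like(x.data)
        np.add.at(dx, (np.arange(n)[:, None, None],
                       np.arange(c)[None, :, None], idx), g)
        x._accum(dx)
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# normalization / dense / losses

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running: dict | None = None, training: bool = True,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over all axes except channel (axis 1)."""
    axes = (0,) + tuple(range(2, x.data.ndim))
    shape = [1] * x.data.ndim
    shape[1] = x.data.shape[1]
    if training:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        if running is not None:
            running["mean"] = ((1 - momentum) * running.get("mean", 0.0)
                               + momentum * mu.ravel())
            running["var"] = ((1 - momentum) * running.get("var", 1.0)
                              + momentum * var.ravel())
    else:
        c = x.data.shape[1]
        # an untrained network has no running statistics yet: fall back to
        # the normalization identity (mean 0, variance 1)
        mu = np.asarray(running.get("mean", np.zeros(c)) if running is not None
                        else np.zeros(c)).reshape(shape)
        var = np.asarray(running.get("var", np.ones(c)) if running is not None
                         else np.ones(c)).reshape(shape)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_d = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    out = Tensor(out_d, parents=(x, gamma, beta))
    m = x.data.size / x.data.shape[1]

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gam = gamma.data.reshape(shape)
            gx = g * gam
            if training:
                dx = (inv / m) * (m * gx
                                  - gx.sum(axis=axes, keepdims=True)
                                  - xhat * (gx * xhat).sum(axis=axes,
                                                           keepdims=True))
            else:
                dx = gx * inv
            x._accum(dx)
    out._backward = bw
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Dense layer: ``x`` (N, F) @ ``w`` (F, O) + ``b`` (O,)."""
    out = x @ w
    if b is not None:
        out = out + b
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax logits."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = z.shape[0]
    loss_val = -logp[np.arange(n), labels].mean()
    out = Tensor(loss_val, parents=(logits,))

    def bw(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accum(g * p / n)
    out._backward = bw
    return out


def bce_with_logits(scores: Tensor, targets: np.ndarray) -> Tensor:
    """Stable binary cross-entropy on raw scores (mean over elements)."""
    s = scores.data
    t = np.asarray(targets, dtype=np.float64)
    loss_val = np.mean(np.maximum(s, 0) - s * t + np.log1p(np.exp(-np.abs(s))))
    out = Tensor(loss_val, parents=(scores,))

    def bw(g):
        sig = 1.0 / (1.0 + np.exp(-np.clip(s, -60, 60)))
        scores._accum(g * (sig - t) / s.size)
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# optimizers

class SGD:
    """SGD with classical momentum and decoupled L2 weight decay."""

    def __init__(self, params: list[Parameter], lr: float,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    """Adam with bias correction (the adaptive-moment optimizer)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def kaiming_init(shape: tuple, fan_in: int, rng: np.random.Generator,
                 gain: float = np.sqrt(2.0)) -> np.ndarray:
    return rng.normal(0.0, gain / np.sqrt(fan_in),
                      size=shape).astype(_DTYPE)
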