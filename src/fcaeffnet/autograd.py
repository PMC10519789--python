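"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small engine: each :class:`Tensor` wraps a ``float32`` ndarray
and records, when gradients are enabled, a vector-Jacobian closure linking it
to its parents.  ``backward()`` walks the graph in reverse topological order.
Only the operations needed by the network family in this package are
implemented (elementwise arithmetic, matmul, reductions, reshaping/slicing,
im2col convolution, depthwise convolution, pooling, the normalisation layers
and the fused softmax cross-entropy).

Gradients accumulate into ``Tensor.grad`` for every node created while
``is_grad_enabled()`` holds; :func:`no_grad` switches the whole engine into
inference mode, in which ops return leaf tensors and build no graph.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from scipy.special import ndtr

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence["Tensor"] = (), _vjp: Callable | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(_parents)
        self._vjp = _vjp

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for long block chains
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
        self.grad = grad.astype(np.float32, copy=False)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=False)
                else:
                    parent.grad = parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -_as_array(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / _as_array(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return narrow(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def _make(data: np.ndarray, parents: Sequence[Tensor], vjp: Callable) -> Tensor:
    if _GRAD_ENABLED and any(p.requires_grad or p._vjp is not None for p in parents):
        return Tensor(data, _parents=parents, _vjp=vjp)
    return Tensor(data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise ---------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data
    return _make(out, (a, b), lambda g: (_unbroadcast(g, a.data.shape),
                                         _unbroadcast(g, b.data.shape)))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data
    return _make(out, (a, b), lambda g: (_unbroadcast(g * b.data, a.data.shape),
                                         _unbroadcast(g * a.data, b.data.shape)))


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** exponent
    return _make(out, (a,), lambda g: (g * exponent * a.data ** (exponent - 1),))


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return _make(out, (a,), lambda g: (g * out,))


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), lambda g: (g / a.data,))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    return _make(s, (a,), lambda g: (g * s * (1.0 - s),))


def swish(a) -> Tensor:
    """x * sigmoid(x) (the SiLU activation)."""
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = a.data * s
    return _make(out, (a,), lambda g: (g * (s + a.data * s * (1.0 - s)),))


_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a) -> Tensor:
    """x * Phi(x) with the exact standard-normal CDF (no tanh approximation)."""
    a = as_tensor(a)
    phi = ndtr(a.data).astype(np.float32)
    out = a.data * phi
    def vjp(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * a.data * a.data)
        return (g * (phi + a.data * pdf),)
    return _make(out, (a,), vjp)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return _make(a.data * mask, (a,), lambda g: (g * mask,))


# -- shape ops -----------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _make(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.data.shape),))


def narrow(a, idx) -> Tensor:
    a = as_tensor(a)
    out = a.data[idx]
    def vjp(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        return (full,)
    return _make(np.ascontiguousarray(out), (a,), vjp)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def vjp(g):
        return tuple(np.ascontiguousarray(p) for p in np.split(g, splits, axis=axis))
    return _make(out, tensors, vjp)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)
    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)
    return _make(out, (a,), vjp)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.mean(axis=axis, keepdims=keepdims, dtype=np.float32)
    denom = a.data.size / out.size
    def vjp(g):
        if axis is None:
            gg = np.broadcast_to(g, a.data.shape)
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            gg = np.broadcast_to(gg, a.data.shape)
        return ((gg / denom).astype(np.float32),)
    return _make(out, (a,), vjp)


def transpose(a, axes: tuple) -> Tensor:
    a = as_tensor(a)
    inv = tuple(np.argsort(axes))
    out = np.ascontiguousarray(a.data.transpose(axes))
    return _make(out, (a,), lambda g: (np.ascontiguousarray(g.transpose(inv)),))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data
    def vjp(g):
        return (g @ b.data.swapaxes(-1, -2), a.data.swapaxes(-1, -2) @ g)
    return _make(out, (a, b), vjp)


# -- convolution ---------------------------------------------------------------

def _pad_hw(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 2-D cross-correlation, NCHW layout, square stride/padding.

    weight: (C_out, C_in, kh, kw); bias: (C_out,) or None.
    1x1/stride-1 convolutions bypass im2col and run as a single tensordot.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, c_in, h, w = x.data.shape
    c_out, c_in_w, kh, kw = weight.data.shape
    if c_in != c_in_w:
        raise ValueError(f"conv2d channel mismatch: input {c_in}, weight expects {c_in_w}")

    if kh == kw == 1 and stride == 1 and padding == 0:
        out = np.tensordot(x.data, weight.data.reshape(c_out, c_in), axes=([1], [1]))
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        def vjp1(g):
            gx = np.tensordot(g, weight.data.reshape(c_out, c_in), axes=([1], [0]))
            gx = np.ascontiguousarray(gx.transpose(0, 3, 1, 2))
            gw = np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3]))
            return gx, gw.reshape(weight.data.shape)
        res = _make(out, (x, weight), vjp1)
    else:
        xp = _pad_hw(x.data, padding, padding)
        ho = (xp.shape[2] - kh) // stride + 1
        wo = (xp.shape[3] - kw) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]           # (n, c, ho, wo, kh, kw)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c_in * kh * kw)
        wmat = weight.data.reshape(c_out, c_in * kh * kw)
        out = (cols @ wmat.T).reshape(n, ho, wo, c_out).transpose(0, 3, 1, 2)
        out = np.ascontiguousarray(out)

        def vjp_dense(g):
            gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, c_out)
            gw = (gmat.T @ cols).reshape(weight.data.shape)
            gcols = (gmat @ wmat).reshape(n, ho, wo, c_in, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += \
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                gxp = gxp[:, :, padding:padding + h, padding:padding + w]
            return np.ascontiguousarray(gxp), gw
        res = _make(out, (x, weight), vjp_dense)

    if bias is not None:
        res = add(res, reshape(as_tensor(bias), (1, c_out, 1, 1)))
    return res


def depthwise_conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Per-channel cross-correlation (groups == channels), NCHW.

    weight: (C, kh, kw).  Also used for the full-extent directional kernels
    (1, W) and (H, 1), where the output collapses to a single column/row.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.data.shape
    cw, kh, kw = weight.data.shape
    if c != cw:
        raise ValueError(f"depthwise channel mismatch: input {c}, weight {cw}")

    if padding == 0 and stride == 1 and (kh, kw) in ((1, w), (h, 1)):
        # full-extent directional kernel: output collapses along one axis and
        # the backward pass is a pure broadcast, no window loop
        if (kh, kw) == (1, w):
            out = np.einsum("nchj,cj->nch", x.data, weight.data[:, 0, :])[..., None]
            def vjp_dir(g):
                g2 = g[..., 0]                               # (n, c, ho)
                gx = g2[..., None] * weight.data[:, None, 0, :]
                gw = np.einsum("nch,nchj->cj", g2, x.data)[:, None, :]
                return np.ascontiguousarray(gx), gw
        else:
            out = np.einsum("ncjw,cj->ncw", x.data, weight.data[:, :, 0])[:, :, None, :]
            def vjp_dir(g):
                g2 = g[:, :, 0, :]                           # (n, c, wo)
                gx = g2[:, :, None, :] * weight.data[:, :, 0][None, :, :, None]
                gw = np.einsum("ncw,ncjw->cj", g2, x.data)[:, :, None]
                return np.ascontiguousarray(gx), gw
        res = _make(np.ascontiguousarray(out), (x, weight), vjp_dir)
        if bias is not None:
            res = add(res, reshape(as_tensor(bias), (1, c, 1, 1)))
        return res

    xp = _pad_hw(x.data, padding, padding)
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    # shift-and-accumulate over the (small) kernel support: avoids building
    # the k^2-times-larger window array that an einsum would need
    out = np.zeros((n, c, ho, wo), dtype=np.float32)
    wd = weight.data
    for i in range(kh):
        for j in range(kw):
            out += xp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] \
                * wd[:, i, j][None, :, None, None]

    def vjp(g):
        gw = np.empty_like(wd)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride]
                gw[:, i, j] = np.einsum("nchw,nchw->c", g, patch, optimize=True)
                gxp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += \
                    g * wd[:, i, j][None, :, None, None]
        if padding:
            gxp = gxp[:, :, padding:padding + h, padding:padding + w]
        return np.ascontiguousarray(gxp), gw
    res = _make(out, (x, weight), vjp)
    if bias is not None:
        res = add(res, reshape(as_tensor(bias), (1, c, 1, 1)))
    return res


def max_pool2d(x, kernel: int, stride: int | None = None) -> Tensor:
    """Non-overlapping max pooling (kernel == stride), NCHW."""
    x = as_tensor(x)
    stride = kernel if stride is None else stride
    if stride != kernel:
        raise NotImplementedError("only kernel == stride pooling is supported")
    n, c, h, w = x.data.shape
    ho, wo = h // kernel, w // kernel
    xv = x.data[:, :, :ho * kernel, :wo * kernel].reshape(n, c, ho, kernel, wo, kernel)
    xw = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, kernel * kernel)
    idx = xw.argmax(axis=-1)
    out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        gwin = np.zeros((n, c, ho, wo, kernel * kernel), dtype=np.float32)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, ho, wo, kernel, kernel).transpose(0, 1, 2, 4, 3, 5)
        gx = gx.reshape(n, c, ho * kernel, wo * kernel)
        if gx.shape[2:] != (h, w):
            full = np.zeros_like(x.data)
            full[:, :, :ho * kernel, :wo * kernel] = gx
            gx = full
        return (np.ascontiguousarray(gx),)
    return _make(np.ascontiguousarray(out), (x,), vjp)


# -- normalisation (fused custom VJPs for speed) --------------------------------

def batch_norm(x, gamma, beta, eps: float) -> Tensor:
    """Training-mode batch normalisation over (N, H, W) per channel."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0, 2, 3)
    m = x.data.size // x.data.shape[1]
    mu = x.data.mean(axis=axes, keepdims=True, dtype=np.float32)
    var = x.data.var(axis=axes, keepdims=True, dtype=np.float32)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    gb = gamma.data[None, :, None, None]
    out = xhat * gb + beta.data[None, :, None, None]

    def vjp(g):
        ggamma = (g * xhat).sum(axis=axes)
        gbeta = g.sum(axis=axes)
        gh = g * gb
        gx = ivar * (gh - gh.mean(axis=axes, keepdims=True)
                     - xhat * (gh * xhat).mean(axis=axes, keepdims=True))
        return gx.astype(np.float32), ggamma, gbeta
    _ = m
    return _make(out.astype(np.float32), (x, gamma, beta), vjp)


def layer_norm(x, gamma, beta, eps: float) -> Tensor:
    """Per-sample normalisation over all of (C, H, W), per-channel affine.

    Statistics never mix samples, so the output for one image is independent
    of whatever else shares its batch.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (1, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True, dtype=np.float32)
    var = x.data.var(axis=axes, keepdims=True, dtype=np.float32)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    gb = gamma.data[None, :, None, None]
    out = xhat * gb + beta.data[None, :, None, None]

    def vjp(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        gh = g * gb
        gx = ivar * (gh - gh.mean(axis=axes, keepdims=True)
                     - xhat * (gh * xhat).mean(axis=axes, keepdims=True))
        return gx.astype(np.float32), ggamma, gbeta
    return _make(out.astype(np.float32), (x, gamma, beta), vjp)


# -- loss ----------------------------------------------------------------------

def softmax_cross_entropy(logits, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12))
    out = np.float32(nll.mean())

    def vjp(g):
        gl = p.copy()
        gl[np.arange(n), labels] -= 1.0
        return ((g * gl / n).astype(np.float32),)
    return _make(out, (logits,), vjp)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)
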