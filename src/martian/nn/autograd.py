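"""Minimal reverse-mode automatic differentiation on numpy arrays.

This engine exists to support training small 2D convolutional GANs on a CPU.
It implements exactly the primitives the generator/discriminator architectures
and the composite loss need: broadcasting arithmetic, elementwise
nonlinearities, axis reductions, zero-padded strided convolution and its
transpose. Gradients are checked against central finite differences in the
test suite.

Convolution is implemented via im2col (``numpy.lib.stride_tricks``) so the
inner loop is a single matmul; col2im is the scatter-add adjoint.
"""

from __future__ import annotations

import numpy as np

# Default compute precision. Single precision roughly halves training time
# and is ample for SGD; gradient-checking tests switch to float64 via
# set_dtype to compare against central differences.
DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


__all__ = [
    "Tensor",
    "set_dtype",
    "as_tensor",
    "conv2d",
    "conv_transpose2d",
    "relu",
    "leaky_relu",
    "tanh",
    "sigmoid",
    "log",
    "absolute",
    "clip",
    "mean",
    "total",
    "instance_norm",
    "reshape",
    "concat",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (adjoint of numpy broadcasting)."""
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
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data, dtype=DTYPE)
        # topological order by DFS
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return self * -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor(self.data ** e, requires_grad=self.requires_grad)
        if out.requires_grad:
            a = self.data

            def bwd(g):
                self._accumulate(g * e * a ** (e - 1.0))

            out._backward, out._parents = bwd, (self,)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _binary(a, b, fwd, da, db) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(fwd(a.data, b.data), requires_grad=a.requires_grad or b.requires_grad)
    if out.requires_grad:
        ad, bd = a.data, b.data

        def bwd(g):
            if a.requires_grad or a._backward is not None:
                a._accumulate(_unbroadcast(da(g, ad, bd), ad.shape))
            if b.requires_grad or b._backward is not None:
                b._accumulate(_unbroadcast(db(g, ad, bd), bd.shape))

        out._backward, out._parents = bwd, (a, b)
    return out


def _unary(x: Tensor, value: np.ndarray, dfn) -> Tensor:
    out = Tensor(value, requires_grad=x.requires_grad)
    if out.requires_grad:
        def bwd(g):
            x._accumulate(dfn(g))

        out._backward, out._parents = bwd, (x,)
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return _unary(x, x.data * mask, lambda g: g * mask)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    factor = np.where(mask, 1.0, slope)
    return _unary(x, x.data * factor, lambda g: g * factor)


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    t = np.tanh(x.data)
    return _unary(x, t, lambda g: g * (1.0 - t * t))


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    return _unary(x, s, lambda g: g * s * (1.0 - s))


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return _unary(x, np.log(x.data), lambda g: g / x.data)


def absolute(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = np.sign(x.data)
    return _unary(x, np.abs(x.data), lambda g: g * s)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient is zero outside [lo, hi] (straight-through inside)."""
    x = as_tensor(x)
    mask = (x.data >= lo) & (x.data <= hi)
    return _unary(x, np.clip(x.data, lo, hi), lambda g: g * mask)


def mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    value = x.data.mean(axis=axis, keepdims=keepdims)
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in np.atleast_1d(axis)])

    def dfn(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, tuple(np.atleast_1d(axis)))
        return np.broadcast_to(g, x.data.shape) / n

    return _unary(x, value, dfn)


def total(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    value = x.data.sum(axis=axis, keepdims=keepdims)

    def dfn(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, tuple(np.atleast_1d(axis)))
        return np.broadcast_to(g, x.data.shape).copy()

    return _unary(x, value, dfn)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Fused per-sample, per-channel spatial normalization with affine.

    x: (N, C, H, W); gamma/beta: broadcastable (1, C, 1, 1). One graph node
    instead of ~20 — instance norm appears after nearly every convolution,
    so the fused backward matters for step time.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data,
                 requires_grad=(x.requires_grad or gamma.requires_grad
                                or beta.requires_grad))
    if out.requires_grad:
        def bwd(g):
            if gamma.requires_grad or gamma._backward is not None:
                gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
            if beta.requires_grad or beta._backward is not None:
                beta._accumulate(_unbroadcast(g, beta.data.shape))
            if x.requires_grad or x._backward is not None:
                dxhat = g * gamma.data
                m1 = dxhat.mean(axis=(2, 3), keepdims=True)
                m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
                x._accumulate(inv * (dxhat - m1 - xhat * m2))

        out._backward, out._parents = bwd, (x, gamma, beta)
    return out


def reshape(x: Tensor, shape) -> Tensor:
    x = as_tensor(x)
    old = x.data.shape
    return _unary(x, x.data.reshape(shape), lambda g: g.reshape(old))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accumulate(piece)

        out._backward, out._parents = bwd, tuple(tensors)
    return out


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, Ho, Wo, C*kh*kw) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N,C,Ho,Wo,kh,kw)
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int):
    """Adjoint of _im2col: scatter-add patches back onto the image grid."""
    n, c, h, w = xshape
    ho, wo = cols.shape[1], cols.shape[2]
    xpad = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    patches = cols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            xpad[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                patches[:, :, i, j]
    if pad:
        return xpad[:, :, pad:h + pad, pad:w + pad]
    return xpad


def _conv_out_size(h: int, k: int, stride: int, pad: int) -> int:
    return (h + 2 * pad - k) // stride + 1


def _conv_bwd_input_s1(g: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Input gradient of a stride-1 conv as a correlation with the flipped
    kernel — avoids materializing the dense gcols matrix that col2im needs
    (a large allocation when the output has few channels, e.g. tanh heads)."""
    o, c, kh, kw = w.shape
    wflip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, kh, kw)
    cols, ho, wo = _im2col(g, kh, kw, 1, kh - 1 - pad)
    wmat = wflip.reshape(c, o * kh * kw)
    gx = cols.reshape(-1, o * kh * kw) @ wmat.T
    return gx.reshape(g.shape[0], ho, wo, c).transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """Cross-correlation: x (N,C,H,W), w (O,C,kh,kw), optional bias (O,)."""
    x, w = as_tensor(x), as_tensor(w)
    o, c, kh, kw = w.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(o, c * kh * kw)
    out_data = cols.reshape(-1, c * kh * kw) @ wmat.T
    out_data = out_data.reshape(x.shape[0], ho, wo, o).transpose(0, 3, 1, 2)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        xshape = x.shape

        def bwd(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(-1, o)
            if w.requires_grad or w._backward is not None:
                gw = gmat.T @ cols.reshape(-1, c * kh * kw)
                w._accumulate(gw.reshape(o, c, kh, kw))
            if x.requires_grad or x._backward is not None:
                if stride == 1:
                    x._accumulate(_conv_bwd_input_s1(g, w.data, pad))
                else:
                    gcols = (gmat @ wmat).reshape(x.shape[0], ho, wo,
                                                  c * kh * kw)
                    x._accumulate(_col2im(gcols, xshape, kh, kw, stride, pad))
            if b is not None and (b.requires_grad or b._backward is not None):
                b._accumulate(g.sum(axis=(0, 2, 3)))

        out._backward, out._parents = bwd, parents
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1, pad: int = 0) -> Tensor:
    """Adjoint of conv2d. x (N,Ci,H,W), w (Ci,Co,kh,kw); output spatial size
    (H-1)*stride - 2*pad + kh."""
    x, w = as_tensor(x), as_tensor(w)
    ci, co, kh, kw = w.shape
    n, _, h, wdt = x.shape
    ho = (h - 1) * stride - 2 * pad + kh
    wo = (wdt - 1) * stride - 2 * pad + kw
    wmat = w.data.reshape(ci, co * kh * kw)
    # forward = col2im of per-pixel weighted kernels
    xmat = x.data.transpose(0, 2, 3, 1).reshape(-1, ci)
    cols = (xmat @ wmat).reshape(n, h, wdt, co * kh * kw)
    out_data = _col2im(cols, (n, co, ho, wo), kh, kw, stride, pad)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, co, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        def bwd(g):
            gcols, _, _ = _im2col(g, kh, kw, stride, pad)  # (N,h,w,co*kh*kw)
            gcols_mat = gcols.reshape(-1, co * kh * kw)
            if x.requires_grad or x._backward is not None:
                gx = (gcols_mat @ wmat.T).reshape(n, h, wdt, ci)
                x._accumulate(gx.transpose(0, 3, 1, 2))
            if w.requires_grad or w._backward is not None:
                gw = xmat.T @ gcols_mat
                w._accumulate(gw.reshape(ci, co, kh, kw))
            if b is not None and (b.requires_grad or b._backward is not None):
                b._accumulate(g.sum(axis=(0, 2, 3)))

        out._backward, out._parents = bwd, parents
    return out
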