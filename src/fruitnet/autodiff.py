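"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine is deliberately small: a :class:`Tensor` wraps a float32
``ndarray`` and records, per operation, a closure that routes the upstream
gradient to its inputs.  ``backward`` runs the closures in reverse
topological order, freeing each interior node's gradient and closure as
soon as it has been consumed so peak memory stays near one layer's working
set.  Only the operations the network needs exist; the convolution and
batch-normalization primitives carry hand-written vector-Jacobian products
because expressing them through elementwise ops would be hopelessly slow.

Inference wraps in :func:`no_grad`, which skips graph construction
entirely.  Everything is deterministic: no threads, plain NumPy.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "no_grad", "conv2d", "depthwise_conv2d", "grouped_conv2d",
           "batchnorm_train", "concat", "same_padding"]

_grad_enabled = [True]


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _grad_enabled[0] = False
    try:
        yield
    finally:
        _grad_enabled[0] = True


def _attach(out: "Tensor", bw) -> None:
    if _grad_enabled[0]:
        out._backward = bw


def _needs_grad(t: "Tensor") -> bool:
    return t.requires_grad or bool(t._prev)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev if _grad_enabled[0] else ()

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs here are deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._prev:
                # interior node: free gradient and closure immediately
                node.grad = None
                node._backward = None
                node._prev = ()

    # -- elementwise arithmetic -------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def bw(g):
            if _needs_grad(self):
                self._accumulate(_unbroadcast(g, self.data.shape))
            if _needs_grad(other):
                other._accumulate(_unbroadcast(g, other.data.shape))

        _attach(out, bw)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, True, (self,))
        _attach(out, lambda g: self._accumulate(-g))
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, True, (self, other))

        def bw(g):
            if _needs_grad(self):
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if _needs_grad(other):
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        _attach(out, bw)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, True, (self, other))

        def bw(g):
            if _needs_grad(self):
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if _needs_grad(other):
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        _attach(out, bw)
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, True, (self, other))

        def bw(g):
            if _needs_grad(self):
                self._accumulate(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape)
                )
            if _needs_grad(other):
                other._accumulate(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape)
                )

        _attach(out, bw)
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, True, (self,))
        _attach(out, lambda g: self._accumulate(g * p * self.data ** (p - 1)))
        return out

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), True, (self,))
        _attach(out, lambda g: self._accumulate(g * out.data))
        return out

    def log(self):
        out = Tensor(np.log(self.data), True, (self,))
        _attach(out, lambda g: self._accumulate(g / self.data))
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), True, (self,))
        _attach(out, lambda g: self._accumulate(g * 0.5 / out.data))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, True, (self,))
        _attach(out, lambda g: self._accumulate(g * out.data * (1.0 - out.data)))
        return out

    def relu6(self):
        out = Tensor(np.clip(self.data, 0.0, 6.0), True, (self,))
        # mask recomputed from the input in the backward pass (not stored)
        _attach(out, lambda g: self._accumulate(
            g * ((self.data > 0.0) & (self.data < 6.0))
        ))
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, True, (self,))

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        _attach(out, bw)
        return out

    # -- reductions / shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        _attach(out, bw)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), True, (self,))
        _attach(out, lambda g: self._accumulate(g.reshape(self.data.shape)))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), True, (self,))
        _attach(out, lambda g: self._accumulate(g.transpose(inv)))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], True, (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        _attach(out, bw)
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), True, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if _needs_grad(t):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    _attach(out, bw)
    return out


# -- convolution / normalization primitives (NHWC) --------------------------

def same_padding(h: int, w: int, kh: int, kw: int, sh: int, sw: int):
    """TensorFlow-style SAME padding: output dims ceil(h/s), ceil(w/s)."""
    oh, ow = -(-h // sh), -(-w // sw)
    ph = max((oh - 1) * sh + kh - h, 0)
    pw = max((ow - 1) * sw + kw - w, 0)
    return (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)


def _im2col(x: np.ndarray, kh, kw, sh, sw, pad):
    (pt, pb), (pl, pr) = pad
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    b, H, W, C = xp.shape
    oh, ow = (H - kh) // sh + 1, (W - kw) // sw + 1
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (b, oh, ow, kh, kw, C), (s0, s1 * sh, s2 * sw, s1, s2, s3)
    )
    return np.ascontiguousarray(cols).reshape(b * oh * ow, kh * kw * C), oh, ow, xp.shape


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """SAME-padded 2D convolution.  x: (b,h,w,cin), w: (kh,kw,cin,cout)."""
    kh, kw, cin, cout = w.data.shape
    bs, h, wdt, _ = x.data.shape
    if kh == 1 and kw == 1 and stride == 1:
        return _conv1x1(x, w, b)
    pad = same_padding(h, wdt, kh, kw, stride, stride)
    cols, oh, ow, pshape = _im2col(x.data, kh, kw, stride, stride, pad)
    wmat = w.data.reshape(kh * kw * cin, cout)
    y = cols @ wmat
    if b is not None:
        y = y + b.data
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(y.reshape(bs, oh, ow, cout), True, prev)

    def bw(g):
        g2 = g.reshape(bs * oh * ow, cout)
        w._accumulate((cols.T @ g2).reshape(w.data.shape))
        if b is not None:
            b._accumulate(g2.sum(axis=0))
        if _needs_grad(x):
            dcols = (g2 @ wmat.T).reshape(bs, oh, ow, kh, kw, cin)
            dxp = np.zeros(pshape, dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + oh * stride : stride, j : j + ow * stride : stride, :] += dcols[:, :, :, i, j, :]
            (pt, _), (pl, _) = pad
            x._accumulate(dxp[:, pt : pt + h, pl : pl + wdt, :])

    _attach(out, bw)
    return out


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution: a matmul over the channel axis, no im2col copy."""
    _, _, cin, cout = w.data.shape
    bs, h, wd, _ = x.data.shape
    wmat = w.data.reshape(cin, cout)
    flat = x.data.reshape(-1, cin)
    y = flat @ wmat
    if b is not None:
        y = y + b.data
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(y.reshape(bs, h, wd, cout), True, prev)

    def bw(g):
        g2 = g.reshape(-1, cout)
        w._accumulate((flat.T @ g2).reshape(w.data.shape))
        if b is not None:
            b._accumulate(g2.sum(axis=0))
        if _needs_grad(x):
            x._accumulate((g2 @ wmat.T).reshape(x.data.shape))

    _attach(out, bw)
    return out


def grouped_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """SAME-padded convolution with independent channel groups.

    x: (b,h,w,c); w: (g, kh, kw, c//g, cout//g).  One im2col plus batched
    matmuls over the group axis.
    """
    g, kh, kw, cgi, cgo = w.data.shape
    bs, h, wdt, c = x.data.shape
    assert c == g * cgi, f"channel mismatch: input {c}, groups {g}x{cgi}"
    pad = same_padding(h, wdt, kh, kw, stride, stride)
    cols, oh, ow, pshape = _im2col(x.data, kh, kw, stride, stride, pad)
    n = bs * oh * ow
    # (n, kh*kw*c) -> (g, n, kh*kw*cgi)
    cols_g = np.ascontiguousarray(
        cols.reshape(n, kh * kw, g, cgi).transpose(2, 0, 1, 3).reshape(g, n, kh * kw * cgi)
    )
    del cols
    wmat = w.data.reshape(g, kh * kw * cgi, cgo)
    y = np.matmul(cols_g, wmat)                       # (g, n, cgo)
    y = y.transpose(1, 0, 2).reshape(bs, oh, ow, g * cgo)
    if b is not None:
        y = y + b.data
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(y, True, prev)

    def bw(grad):
        g2 = np.ascontiguousarray(
            grad.reshape(n, g, cgo).transpose(1, 0, 2)
        )                                             # (g, n, cgo)
        w._accumulate(np.matmul(cols_g.transpose(0, 2, 1), g2).reshape(w.data.shape))
        if b is not None:
            b._accumulate(grad.sum(axis=(0, 1, 2)))
        if _needs_grad(x):
            dcols_g = np.matmul(g2, wmat.transpose(0, 2, 1))  # (g, n, kh*kw*cgi)
            dcols = dcols_g.reshape(g, n, kh * kw, cgi).transpose(1, 2, 0, 3).reshape(
                bs, oh, ow, kh, kw, c
            )
            dxp = np.zeros(pshape, dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + oh * stride : stride, j : j + ow * stride : stride, :] += dcols[:, :, :, i, j, :]
            (pt, _), (pl, _) = pad
            x._accumulate(dxp[:, pt : pt + h, pl : pl + wdt, :])

    _attach(out, bw)
    return out


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused batch normalization over (b,h,w); returns (out, batch_mean, batch_var)."""
    axes = (0, 1, 2)
    n = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
    mu = x.data.mean(axis=axes)
    d = x.data - mu
    var = np.einsum("bhwc,bhwc->c", d, d) / n
    inv = 1.0 / np.sqrt(var + eps)
    d *= inv  # d is now xhat; recomputed in bw from the output to avoid retention
    out = Tensor(d * gamma.data + beta.data, True, (x, gamma, beta))
    del d

    def bw(g):
        # gamma is never exactly 0 in practice (initialized at 1); the guard
        # only avoids a division error in that degenerate case
        xhat = (out.data - beta.data) / np.where(gamma.data == 0.0, 1.0, gamma.data)
        beta._accumulate(g.sum(axis=axes))
        gamma._accumulate(np.einsum("bhwc,bhwc->c", g, xhat))
        if _needs_grad(x):
            gx = g * gamma.data
            m1 = gx.mean(axis=axes)
            m2 = np.einsum("bhwc,bhwc->c", gx, xhat) / n
            x._accumulate((gx - m1 - xhat * m2) * inv)

    _attach(out, bw)
    return out, mu, var


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """SAME-padded depthwise convolution.  w: (kh,kw,c), one filter per channel."""
    kh, kw, c = w.data.shape
    bs, h, wdt, cx = x.data.shape
    assert cx == c, f"channel mismatch: input {cx}, kernel {c}"
    pad = same_padding(h, wdt, kh, kw, stride, stride)
    (pt, pb), (pl, pr) = pad
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    oh, ow = -(-h // stride), -(-wdt // stride)
    y = np.zeros((bs, oh, ow, c), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            y += xp[:, i : i + oh * stride : stride, j : j + ow * stride : stride, :] * w.data[i, j]
    if b is not None:
        y += b.data
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(y, True, prev)

    def bw(g):
        dw = np.empty_like(w.data)
        need_dx = _needs_grad(x)
        dxp = np.zeros_like(xp) if need_dx else None
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i : i + oh * stride : stride, j : j + ow * stride : stride, :]
                dw[i, j] = np.einsum("bhwc,bhwc->c", patch, g)
                if need_dx:
                    dxp[:, i : i + oh * stride : stride, j : j + ow * stride : stride, :] += g * w.data[i, j]
        w._accumulate(dw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if need_dx:
            x._accumulate(dxp[:, pt : pt + h, pl : pl + wdt, :])

    _attach(out, bw)
    return out
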