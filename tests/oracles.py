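"""Independent straight-line reference implementations used as oracles.

Everything here is written with explicit loops or elementary NumPy steps,
deliberately sharing no code with the package's layer library, so that an
agreement between the two routes is evidence of correctness rather than of
shared bugs.
"""

from __future__ import annotations

import numpy as np


def loop_directional_mean(x: np.ndarray, axis: str) -> np.ndarray:
    b, h, w, c = x.shape
    if axis == "horizontal":      # mean over columns: one value per (row, channel)
        out = np.zeros((b, h, 1, c))
        for bi in range(b):
            for i in range(h):
                for ch in range(c):
                    s = 0.0
                    for j in range(w):
                        s += x[bi, i, j, ch]
                    out[bi, i, 0, ch] = s / w
        return out
    out = np.zeros((b, 1, w, c))
    for bi in range(b):
        for j in range(w):
            for ch in range(c):
                s = 0.0
                for i in range(h):
                    s += x[bi, i, j, ch]
                out[bi, 0, j, ch] = s / h
    return out


def loop_global_mean(x: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of z_c = (1/(h*w)) sum_j sum_i x_c(i, j)."""
    b, h, w, c = x.shape
    out = np.zeros((b, c))
    for bi in range(b):
        for ch in range(c):
            s = 0.0
            for i in range(h):
                for j in range(w):
                    s += x[bi, i, j, ch]
            out[bi, ch] = s / (h * w)
    return out


def loop_cross_spatial_maps(t1: np.ndarray, t3: np.ndarray):
    """Explicit vector-matrix products for the two attention maps."""
    n, h, w, cg = t1.shape
    m1 = np.zeros((n, h, w))
    m2 = np.zeros((n, h, w))
    for ni in range(n):
        v1 = _softmax1d(loop_global_mean(t1[ni : ni + 1])[0])
        v3 = _softmax1d(loop_global_mean(t3[ni : ni + 1])[0])
        for i in range(h):
            for j in range(w):
                m1[ni, i, j] = sum(v1[c] * t3[ni, i, j, c] for c in range(cg))
                m2[ni, i, j] = sum(v3[c] * t1[ni, i, j, c] for c in range(cg))
    return m1, m2


def _softmax1d(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def _same_pad_amounts(h, w, k, s):
    oh, ow = -(-h // s), -(-w // s)
    ph = max((oh - 1) * s + k - h, 0)
    pw = max((ow - 1) * s + k - w, 0)
    return (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2), oh, ow


def loop_conv2d(x: np.ndarray, w: np.ndarray, bias=None, stride: int = 1) -> np.ndarray:
    """Naive SAME-padded convolution; w: (kh, kw, cin, cout)."""
    b, h, wd, cin = x.shape
    kh, kw, _, cout = w.shape
    (pt, pb), (pl, pr), oh, ow = _same_pad_amounts(h, wd, kh, stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    out = np.zeros((b, oh, ow, cout))
    for bi in range(b):
        for oi in range(oh):
            for oj in range(ow):
                patch = xp[bi, oi * stride : oi * stride + kh, oj * stride : oj * stride + kw, :]
                for co in range(cout):
                    out[bi, oi, oj, co] = np.sum(patch * w[:, :, :, co])
    if bias is not None:
        out += bias
    return out


def loop_depthwise_conv2d(x: np.ndarray, w: np.ndarray, bias=None, stride: int = 1) -> np.ndarray:
    """Naive SAME-padded depthwise convolution; w: (kh, kw, c)."""
    b, h, wd, c = x.shape
    kh, kw, _ = w.shape
    (pt, pb), (pl, pr), oh, ow = _same_pad_amounts(h, wd, kh, stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    out = np.zeros((b, oh, ow, c))
    for bi in range(b):
        for oi in range(oh):
            for oj in range(ow):
                for ch in range(c):
                    patch = xp[bi, oi * stride : oi * stride + kh,
                               oj * stride : oj * stride + kw, ch]
                    out[bi, oi, oj, ch] = np.sum(patch * w[:, :, ch])
    if bias is not None:
        out += bias
    return out


def _bn_eval(x, gamma, beta, mean, var, eps=1e-3):
    return (x - mean) / np.sqrt(var + eps) * gamma + beta


def reference_bottleneck_forward(block, x: np.ndarray) -> np.ndarray:
    """Inference-mode forward of a built Bottleneck using only loop convs."""
    spec = block.spec
    h = x.astype(np.float64)
    if block.expand is not None:
        h = loop_conv2d(h, block.expand.weight.data.astype(np.float64))
        bn = block.expand_bn
        h = _bn_eval(h, bn.gamma.data, bn.beta.data, bn.running_mean, bn.running_var, bn.eps)
        h = np.clip(h, 0, 6)
    if spec.multi_branch:
        fused = None
        for conv, bn in zip(block.branches, block.branch_bns):
            br = loop_depthwise_conv2d(
                h, conv.weight.data.astype(np.float64),
                bias=None if conv.bias is None else conv.bias.data,
            )
            br = _bn_eval(br, bn.gamma.data, bn.beta.data, bn.running_mean, bn.running_var, bn.eps)
            br = np.clip(br, 0, 6)
            fused = br if fused is None else fused + br
        h = fused
    else:
        h = loop_depthwise_conv2d(h, block.dw.weight.data.astype(np.float64), stride=spec.stride)
        bn = block.dw_bn
        h = _bn_eval(h, bn.gamma.data, bn.beta.data, bn.running_mean, bn.running_var, bn.eps)
        h = np.clip(h, 0, 6)
    h = loop_conv2d(h, block.project.weight.data.astype(np.float64))
    bn = block.project_bn
    h = _bn_eval(h, bn.gamma.data, bn.beta.data, bn.running_mean, bn.running_var, bn.eps)
    if spec.use_residual:
        h = h + x
    return h


def reference_ema_forward(ema, x: np.ndarray) -> np.ndarray:
    """Straight-line inference-mode reimplementation of the EMA module, using
    only elementary NumPy steps and the module's raw weight arrays."""
    g = ema.cfg.groups
    b, h, w, c = x.shape
    cg = c // g
    x64 = x.astype(np.float64)

    # dense 1x1 channel mixer + bias
    w1 = ema.conv1x1.weight.data.reshape(c, c).astype(np.float64)
    t1 = np.tensordot(x64, w1, axes=([3], [0])) + ema.conv1x1.bias.data
    # scale-only group normalization
    t1g = t1.reshape(b, h, w, g, cg)
    mu = t1g.mean(axis=(1, 2, 4), keepdims=True)
    var = ((t1g - mu) ** 2).mean(axis=(1, 2, 4), keepdims=True)
    t1 = ((t1g - mu) / np.sqrt(var + ema.norm.eps)).reshape(b, h, w, c) * ema.norm.gamma.data
    # directional sigmoid gates
    gh = 1 / (1 + np.exp(-t1.mean(axis=2, keepdims=True)))
    gw = 1 / (1 + np.exp(-t1.mean(axis=1, keepdims=True)))
    t1 = t1 * gh * gw

    # grouped 3x3 path
    if g > 1:
        w3 = ema.conv3x3.weight.data.astype(np.float64)   # (g, 3, 3, cg, cg)
        t3 = np.zeros_like(x64)
        for gi in range(g):
            xg = x64[..., gi * cg : (gi + 1) * cg]
            t3[..., gi * cg : (gi + 1) * cg] = loop_conv2d(xg, w3[gi])
        t3 += ema.conv3x3.bias.data
    else:
        t3 = loop_conv2d(x64, ema.conv3x3.weight.data.astype(np.float64),
                         bias=ema.conv3x3.bias.data)

    def fold(t):
        return t.reshape(b, h, w, g, cg).transpose(0, 3, 1, 2, 4).reshape(b * g, h, w, cg)

    T1, T3, Xg = fold(t1), fold(t3), fold(x64)
    v1 = np.stack([_softmax1d(T1[i].mean(axis=(0, 1))) for i in range(b * g)])
    v3 = np.stack([_softmax1d(T3[i].mean(axis=(0, 1))) for i in range(b * g)])
    m1 = np.einsum("nc,nhwc->nhw", v1, T3)
    m2 = np.einsum("nc,nhwc->nhw", v3, T1)
    gate = 1 / (1 + np.exp(-(m1 + m2)))
    out = Xg * gate[..., None]
    return out.reshape(b, g, h, w, cg).transpose(0, 2, 3, 1, 4).reshape(b, h, w, c)
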