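"""Efficient multi-scale attention (EMA) with cross-spatial learning.

The module splits the channel axis into ``g`` groups, runs a 1×1
channel-mixing path (gated by one-dimensional horizontal and vertical
average pooling) and a 3×3 group-convolution path in parallel, and builds
two spatial attention maps per group by multiplying the softmax-normalized
globally pooled descriptor of one path with the spatially flattened other
path.  The summed maps pass through a sigmoid and gate the input features,
so the output has exactly the input's shape and the gate is bounded in
(0, 1).

The functional operations (:func:`split_into_groups`,
:func:`pool_directional`, :func:`pool_global`, :func:`cross_spatial_maps`)
are plain-NumPy and shared by tests and the trainable :class:`EMA` module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import Conv2d, GroupedConv2d, GroupNormScale, Module

__all__ = [
    "EMAConfig", "EMA", "split_into_groups", "pool_directional",
    "pool_global", "cross_spatial_maps",
]


@dataclass(frozen=True)
class EMAConfig:
    """channels: feature-map width c; groups: number of channel groups g (default 8)."""

    channels: int
    groups: int = 8

    def __post_init__(self):
        if self.groups < 1:
            raise ValueError(f"groups must be >= 1, got {self.groups}")
        if self.channels % self.groups:
            raise ValueError(
                f"channel count c={self.channels} is not divisible by g={self.groups}"
            )


def split_into_groups(x: np.ndarray, g: int) -> list[np.ndarray]:
    """Split (b,h,w,c) into g sub-maps of c//g channels, order preserved."""
    c = x.shape[-1]
    if c % g:
        raise ValueError(f"channel count c={c} is not divisible by g={g}")
    return [x[..., i * (c // g) : (i + 1) * (c // g)] for i in range(g)]


def pool_directional(x: np.ndarray, axis: str) -> np.ndarray:
    """1-D average pooling: 'horizontal' = mean over columns -> (b,h,1,c);
    'vertical' = mean over rows -> (b,1,w,c)."""
    if x.size == 0:
        raise ValueError("empty feature map")
    if axis == "horizontal":
        return x.mean(axis=2, keepdims=True)
    if axis == "vertical":
        return x.mean(axis=1, keepdims=True)
    raise ValueError(f"unknown pooling axis {axis!r}; expected 'horizontal' or 'vertical'")


def pool_global(x: np.ndarray) -> np.ndarray:
    """2-D global average pooling: mean over all h*w positions -> (b, c)."""
    return x.mean(axis=(1, 2))


def _softmax(v: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(v - v.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def cross_spatial_maps(t1: np.ndarray, t3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two cross-spatial attention maps from the parallel branch outputs.

    Both inputs are (n, h, w, cg) where n folds batch and group.  Map 1 is
    softmax(global-pool(t1)) — a 1×cg weighting row vector — times t3
    flattened to cg×(h·w), reshaped back to (n, h, w); map 2 swaps the roles.
    Returned before the sigmoid aggregation.
    """
    if t1.shape != t3.shape:
        raise ValueError(f"branch shape mismatch: {t1.shape} vs {t3.shape}")
    n, h, w, cg = t1.shape
    v1 = _softmax(pool_global(t1))                       # (n, cg)
    v3 = _softmax(pool_global(t3))
    m1 = np.einsum("nc,nhwc->nhw", v1, t3)
    m2 = np.einsum("nc,nhwc->nhw", v3, t1)
    return m1, m2


class EMA(Module):
    """Trainable EMA block; output shape equals input shape.

    The 1×1 path is a dense channel mixer followed by scale-only group
    normalization and multiplicative directional gating; the 3×3 path is a
    group convolution (one 3×3 mixer per channel group).  Transform widths
    were fixed by the published parameter budget of the full model.
    """

    def __init__(self, rng: np.random.Generator, cfg: EMAConfig):
        cfg.__post_init__()  # re-validate (dataclass may be built via replace)
        self.cfg = cfg
        c, g = cfg.channels, cfg.groups
        self.conv1x1 = Conv2d(rng, c, c, kernel=1, bias=True)
        self.norm = GroupNormScale(c, groups=g)
        self.conv3x3 = (
            GroupedConv2d(rng, c, c, kernel=3, groups=g, bias=True)
            if g > 1
            else Conv2d(rng, c, c, kernel=3, bias=True)
        )

    def _fold_groups(self, t: Tensor) -> Tensor:
        b, h, w, c = t.shape
        g = self.cfg.groups
        return t.reshape(b, h, w, g, c // g).transpose((0, 3, 1, 2, 4)).reshape(b * g, h, w, c // g)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        b, h, w, c = x.shape
        g = self.cfg.groups
        if c != self.cfg.channels:
            raise ValueError(f"expected {self.cfg.channels} channels, got {c}")

        t1 = self.norm(self.conv1x1(x, training), training)
        # directional gating: sigmoid of row/column means, broadcast-multiplied
        gate_h = t1.mean(axis=2, keepdims=True).sigmoid()   # (b,h,1,c)
        gate_w = t1.mean(axis=1, keepdims=True).sigmoid()   # (b,1,w,c)
        t1 = t1 * gate_h * gate_w
        t3 = self.conv3x3(x, training)

        T1 = self._fold_groups(t1)                          # (b*g, h, w, cg)
        T3 = self._fold_groups(t3)
        cg = c // g
        v1 = T1.mean(axis=(1, 2)).softmax(axis=-1)          # (b*g, cg)
        v3 = T3.mean(axis=(1, 2)).softmax(axis=-1)
        m1 = (T3.reshape(b * g, h * w, cg) @ v1.reshape(b * g, cg, 1)).reshape(b * g, h, w, 1)
        m2 = (T1.reshape(b * g, h * w, cg) @ v3.reshape(b * g, cg, 1)).reshape(b * g, h, w, 1)
        gate = (m1 + m2).sigmoid()                          # (b*g, h, w, 1), values in (0,1)

        Xg = self._fold_groups(x)
        out = Xg * gate
        return out.reshape(b, g, h, w, cg).transpose((0, 2, 3, 1, 4)).reshape(b, h, w, c)

    # closed-form audit used by the model-level parameter breakdown
    @staticmethod
    def param_count_formula(cfg: EMAConfig) -> int:
        c, g = cfg.channels, cfg.groups
        cg = c // g
        conv1 = c * c + c                  # dense 1x1 mixer + bias
        conv3 = g * (9 * cg * cg) + c      # grouped 3x3 mixer + bias
        norm = c                           # scale-only group norm
        return conv1 + conv3 + norm
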