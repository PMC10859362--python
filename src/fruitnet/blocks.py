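"""Inverted-residual bottlenecks and the Res-Inception variant.

A standard MobileNetV2 bottleneck expands channels by a factor ``t`` with a
pointwise convolution, filters them with a 3×3 depthwise convolution, and
projects back linearly, adding a skip connection at stride 1 when input and
output widths match.  The Res-Inception variant replaces the single 3×3
depthwise stage at stride 1 with parallel larger depthwise kernels
(default 5×5 and 7×7), each with bias and its own batch normalization,
fused by element-wise sum; at stride != 1 the block falls back to the
original depthwise-separable unit unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import BatchNorm2d, Conv2d, DepthwiseConv2d, Module

__all__ = ["ConvSpec", "BlockSpec", "Bottleneck", "block_param_count"]


@dataclass(frozen=True)
class ConvSpec:
    """One convolution: kernel D_k (square, odd), M -> N channels, stride s."""

    kernel: int
    in_channels: int
    out_channels: int
    stride: int = 1
    depthwise: bool = False
    bias: bool = False

    def __post_init__(self):
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError(f"kernel size must be odd and positive, got {self.kernel}")
        if self.depthwise and self.in_channels != self.out_channels:
            raise ValueError("depthwise convolution requires N == M")

    def param_count(self) -> int:
        if self.depthwise:
            n = self.kernel ** 2 * self.in_channels
        else:
            n = self.kernel ** 2 * self.in_channels * self.out_channels
        if self.bias:
            n += self.out_channels
        return n


@dataclass(frozen=True)
class BlockSpec:
    """One bottleneck: expansion t, stride in {1,2}, multi-scale kernel set.

    ``res_inception`` selects the parallel-kernel depthwise stage (only
    effective at stride 1); the residual skip requires stride 1 and matching
    channel widths.
    """

    in_channels: int
    out_channels: int
    stride: int = 1
    expansion: int = 6
    kernel_set: tuple[int, ...] = (5, 7)
    res_inception: bool = True
    branch_bias: bool = True

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if not self.kernel_set:
            raise ValueError("kernel_set must be non-empty")

    @property
    def use_residual(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels

    @property
    def multi_branch(self) -> bool:
        return self.res_inception and self.stride == 1

    @property
    def expanded(self) -> int:
        return self.in_channels * self.expansion


class Bottleneck(Module):
    """Built block; at stride != 1 (or res_inception=False) it is bit-identical
    in structure to the plain inverted residual."""

    def __init__(self, rng: np.random.Generator, spec: BlockSpec):
        self.spec = spec
        ce = spec.expanded
        if spec.expansion != 1:
            self.expand = Conv2d(rng, spec.in_channels, ce, kernel=1)
            self.expand_bn = BatchNorm2d(ce)
        else:
            self.expand = None
        if spec.multi_branch:
            self.branches = [
                DepthwiseConv2d(rng, ce, k, stride=1, bias=spec.branch_bias)
                for k in spec.kernel_set
            ]
            self.branch_bns = [BatchNorm2d(ce) for _ in spec.kernel_set]
        else:
            self.dw = DepthwiseConv2d(rng, ce, 3, stride=spec.stride)
            self.dw_bn = BatchNorm2d(ce)
        self.project = Conv2d(rng, ce, spec.out_channels, kernel=1)
        self.project_bn = BatchNorm2d(spec.out_channels)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        spec = self.spec
        if x.shape[-1] != spec.in_channels:
            raise ValueError(
                f"channel mismatch: block expects {spec.in_channels}, got {x.shape[-1]}"
            )
        h = x
        if self.expand is not None:
            h = self.expand_bn(self.expand(h, training), training).relu6()
        if spec.multi_branch:
            fused = None
            for conv, bn in zip(self.branches, self.branch_bns):
                branch = bn(conv(h, training), training).relu6()
                fused = branch if fused is None else fused + branch
            h = fused
        else:
            h = self.dw_bn(self.dw(h, training), training).relu6()
        h = self.project_bn(self.project(h, training), training)
        if spec.use_residual:
            h = h + x
        return h


def block_param_count(spec: BlockSpec) -> int:
    """Closed-form trainable-parameter count of one block (BN = 2 per channel;
    running statistics are not trainable and not counted)."""
    ce = spec.expanded
    n = 0
    if spec.expansion != 1:
        n += ConvSpec(1, spec.in_channels, ce).param_count() + 2 * ce
    if spec.multi_branch:
        for k in spec.kernel_set:
            n += ConvSpec(k, ce, ce, depthwise=True, bias=spec.branch_bias).param_count()
            n += 2 * ce
    else:
        n += ConvSpec(3, ce, ce, stride=spec.stride, depthwise=True).param_count() + 2 * ce
    n += ConvSpec(1, ce, spec.out_channels).param_count() + 2 * spec.out_channels
    return n
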