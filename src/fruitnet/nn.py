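"""Layer library on top of the autodiff engine.

Layers follow the Keras/TensorFlow conventions the backbone assumes:
NHWC data layout, SAME padding, ReLU6 clamping, batch normalization with
trainable scale/offset and *non-trainable* running statistics (excluded
from every parameter count).
"""

from __future__ import annotations

import numpy as np

from .autodiff import (Tensor, batchnorm_train, conv2d, depthwise_conv2d,
                       grouped_conv2d)

__all__ = [
    "Module", "Conv2d", "DepthwiseConv2d", "GroupedConv2d", "BatchNorm2d",
    "GroupNormScale", "Dense", "ReLU6", "Adam", "cross_entropy_logits",
]


class Module:
    """Base class: child modules and parameters are discovered by attribute."""

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.forward(x, training)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:  # pragma: no cover
        raise NotImplementedError

    def modules(self):
        """Yield self and all descendant modules."""
        yield self
        for _, child in self._children():
            yield from child.modules()

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Tensor]:
        out = []
        for val in vars(self).values():
            if isinstance(val, Tensor) and val.requires_grad:
                out.append(val)
        for _, child in self._children():
            out.extend(child.parameters())
        return out

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield f"{prefix}{name}", val
        for name, child in self._children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield f"{prefix}{name}", val
        for name, child in self._children():
            yield from child.named_buffers(f"{prefix}{name}.")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, arr in state.items():
            if key in params:
                params[key].data = np.asarray(arr, dtype=np.float32).reshape(params[key].data.shape)
            elif key in bufs:
                bufs[key][...] = arr
            else:
                raise KeyError(f"unknown parameter {key!r} in checkpoint")


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, stride: int = 1, bias: bool = False):
        fan_in = kernel * kernel * in_ch
        self.stride = stride
        self.weight = Tensor(_he_normal(rng, (kernel, kernel, in_ch, out_ch), fan_in), True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), True) if bias else None

    def forward(self, x, training=False):
        return conv2d(x, self.weight, self.bias, self.stride)


class DepthwiseConv2d(Module):
    def __init__(self, rng, ch: int, kernel: int, stride: int = 1, bias: bool = False):
        fan_in = kernel * kernel
        self.stride = stride
        self.weight = Tensor(_he_normal(rng, (kernel, kernel, ch), fan_in), True)
        self.bias = Tensor(np.zeros(ch, np.float32), True) if bias else None

    def forward(self, x, training=False):
        return depthwise_conv2d(x, self.weight, self.bias, self.stride)


class GroupedConv2d(Module):
    """Convolution with ``groups`` independent channel blocks (c divisible by groups)."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, groups: int,
                 stride: int = 1, bias: bool = False):
        if in_ch % groups or out_ch % groups:
            raise ValueError(f"groups={groups} must divide in/out channels ({in_ch}, {out_ch})")
        self.groups = groups
        self.stride = stride
        cg_in, cg_out = in_ch // groups, out_ch // groups
        fan_in = kernel * kernel * cg_in
        self.weight = Tensor(_he_normal(rng, (groups, kernel, kernel, cg_in, cg_out), fan_in), True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), True) if bias else None

    def forward(self, x, training=False):
        return grouped_conv2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-3, momentum: float = 0.9):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(ch, np.float32), True)
        self.beta = Tensor(np.zeros(ch, np.float32), True)
        self.running_mean = np.zeros(ch, np.float32)  # buffers, not parameters
        self.running_var = np.ones(ch, np.float32)

    def forward(self, x, training=False):
        if training:
            out, mu, var = batchnorm_train(x, self.gamma, self.beta, self.eps)
            mom = self.momentum
            self.running_mean[...] = mom * self.running_mean + (1 - mom) * mu
            self.running_var[...] = mom * self.running_var + (1 - mom) * var
            return out
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        return x * Tensor(scale) + Tensor(self.beta.data - self.running_mean * scale)


class GroupNormScale(Module):
    """Group normalization with a per-channel scale only (no offset).

    Normalizes each of ``groups`` channel blocks over (h, w, c//g) and
    rescales channels with a learnable gamma of length c.
    """

    def __init__(self, ch: int, groups: int, eps: float = 1e-5):
        if ch % groups:
            raise ValueError(f"groups={groups} must divide channels ({ch})")
        self.groups = groups
        self.eps = eps
        self.gamma = Tensor(np.ones(ch, np.float32), True)

    def forward(self, x, training=False):
        b, h, w, c = x.shape
        g = self.groups
        xg = x.reshape(b, h, w, g, c // g)
        m = xg.mean(axis=(1, 2, 4), keepdims=True)
        d = xg - m
        v = (d * d).mean(axis=(1, 2, 4), keepdims=True)
        xhat = (d * ((v + self.eps) ** -0.5)).reshape(b, h, w, c)
        return xhat * self.gamma


class Dense(Module):
    def __init__(self, rng, in_features: int, out_features: int, bias: bool = True):
        self.weight = Tensor(_he_normal(rng, (in_features, out_features), in_features), True)
        self.bias = Tensor(np.zeros(out_features, np.float32), True) if bias else None

    def forward(self, x, training=False):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class ReLU6(Module):
    def forward(self, x, training=False):
        return x.relu6()


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from logits, with a fused backward."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.data.shape[0]
    idx = np.arange(n)
    out = Tensor(-logp[idx, labels].mean(), True, (logits,))

    def bw(g):
        p = np.exp(logp)
        p[idx, labels] -= 1.0
        logits._accumulate(g * p / n)

    out._backward = bw
    return out


class Adam:
    """Adam with TensorFlow-default hyperparameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= lr_t * m / (np.sqrt(v) + self.eps)
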