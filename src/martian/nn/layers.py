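"""Neural-network layers composed from the autograd primitives."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: children discovered by attribute scan, torch-style."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype).copy()


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad = stride, pad
        self.weight = _he_init(rng, (c_out, c_in, kernel, kernel),
                               c_in * kernel * kernel)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad = stride, pad
        self.weight = _he_init(rng, (c_in, c_out, kernel, kernel),
                               c_in * kernel * kernel)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                   self.pad)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.instance_norm(x, self.gamma, self.beta, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ag.leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.tanh(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ResidualBlock(Module):
    """conv-IN-ReLU-conv-IN with an identity shortcut (3x3 kernels)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, pad=1, rng=rng)
        self.norm1 = InstanceNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, pad=1, rng=rng)
        self.norm2 = InstanceNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        h = ag.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return x + h


class GlobalMean(Module):
    """Average over channel and spatial axes -> one scalar per sample."""

    def forward(self, x: Tensor) -> Tensor:
        return ag.mean(x, axis=(1, 2, 3))
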