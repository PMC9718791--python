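"""Generator and discriminator architectures.

The generator is a residual image-translation network: three stride-2
down-sampling blocks, an 8-block residual bottleneck, three up-sampling
blocks, and a tanh head bounding the output to [-1, 1]. There are **no**
encoder-decoder skip connections: a skip path lets input streaks leak
straight into the output, which is exactly what an artifact-removal
translator must not do. The residual blocks keep their internal identity
shortcuts.

The discriminator is five stride-2 convolution blocks followed by a global
sigmoid realness score (a patch-wise head is available behind a flag).

Layer details not fixed by the architecture sketch follow the standard
residual-translation recipe: 4x4 kernels in sampling blocks, 3x3 in residual
blocks, instance normalization, ReLU (leaky in the discriminator), channel
width doubling per down-sampling block.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import (Conv2d, ConvTranspose2d, GlobalMean, InstanceNorm2d,
                        LeakyReLU, Module, ReLU, ResidualBlock, Sequential,
                        Sigmoid, Tanh)

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class GeneratorSpec:
    n_down: int = 3
    n_residual: int = 8
    n_up: int = 3
    base_channels: int = 64          # 16 at desk scale
    output_activation: str = "tanh"  # bounded to [-1, 1]

    def __post_init__(self):
        if self.n_up != self.n_down:
            raise ValueError("n_up must equal n_down (shape preservation)")
        if self.n_down < 0 or self.n_residual < 0:
            raise ValueError("block counts must be non-negative")


@dataclass(frozen=True)
class DiscriminatorSpec:
    n_down: int = 5
    base_channels: int = 64
    patch_output: bool = False  # global sigmoid score by default

    def __post_init__(self):
        if self.n_down < 1:
            raise ValueError("need at least one down-sampling block")


class _GeneratorNet(Module):
    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        c = spec.base_channels
        layers: list[Module] = [Conv2d(1, c, 7, pad=3, rng=rng),
                                InstanceNorm2d(c), ReLU()]
        for _ in range(spec.n_down):
            layers += [Conv2d(c, c * 2, 4, stride=2, pad=1, rng=rng),
                       InstanceNorm2d(c * 2), ReLU()]
            c *= 2
        for _ in range(spec.n_residual):
            layers.append(ResidualBlock(c, rng))
        for _ in range(spec.n_up):
            layers += [ConvTranspose2d(c, c // 2, 4, stride=2, pad=1, rng=rng),
                       InstanceNorm2d(c // 2), ReLU()]
            c //= 2
        layers += [Conv2d(c, 1, 7, pad=3, rng=rng), Tanh()]
        self.net = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class _DiscriminatorNet(Module):
    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        c_in, c = 1, spec.base_channels
        layers: list[Module] = []
        for i in range(spec.n_down):
            layers.append(Conv2d(c_in, c, 4, stride=2, pad=1, rng=rng))
            if i > 0:
                layers.append(InstanceNorm2d(c))
            layers.append(LeakyReLU(0.2))
            c_in, c = c, min(c * 2, spec.base_channels * 8)
        layers.append(Conv2d(c_in, 1, 3, pad=1, rng=rng))
        if not spec.patch_output:
            layers.append(GlobalMean())
        layers.append(Sigmoid())
        self.net = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


def _as_batch(images: np.ndarray) -> tuple[np.ndarray, bool]:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        return images[None, None], True
    if images.ndim == 3:  # (N, H, W)
        return images[:, None], False
    if images.ndim == 4:
        return images, False
    raise ValueError("expected 2D image, (N,H,W) or (N,C,H,W) batch")


class GeneratorFunction:
    """A trained (or trainable) normalized-image -> normalized-image mapping."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.step = 0
        self.net = _GeneratorNet(spec, np.random.default_rng(seed))

    def _check_size(self, h: int, w: int) -> None:
        f = 2 ** self.spec.n_down
        if h % f or w % f:
            raise ValueError(
                f"spatial size ({h}, {w}) not divisible by 2^n_down = {f}")

    def forward_tensor(self, x: Tensor) -> Tensor:
        self._check_size(x.shape[2], x.shape[3])
        return self.net(x)

    def __call__(self, images: np.ndarray) -> np.ndarray:
        batch, squeeze = _as_batch(images)
        self._check_size(batch.shape[2], batch.shape[3])
        out = self.net(Tensor(batch)).data
        return out[0, 0] if squeeze else out

    def parameters(self):
        return self.net.parameters()

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str) -> None:
        meta = {"format_version": CHECKPOINT_FORMAT_VERSION, "kind": "generator",
                "spec": asdict(self.spec), "seed": self.seed, "step": self.step}
        arrays = {f"p{i}": a for i, a in enumerate(self.net.state_arrays())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "GeneratorFunction":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
                raise ValueError("unsupported checkpoint format version")
            spec = GeneratorSpec(**meta["spec"])
            gen = cls(spec, seed=meta.get("seed", 0))
            gen.step = meta.get("step", 0)
            arrays = [data[f"p{i}"]
                      for i in range(len([k for k in data.files if k != "meta"]))]
            gen.net.load_state_arrays(arrays)
        return gen


class DiscriminatorFunction:
    """Realness scorer: normalized image(s) -> score(s) strictly in (0, 1)."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.net = _DiscriminatorNet(spec, np.random.default_rng(seed))

    def forward_tensor(self, x: Tensor) -> Tensor:
        return self.net(x)

    def __call__(self, images: np.ndarray) -> np.ndarray:
        batch, squeeze = _as_batch(images)
        out = self.net(Tensor(batch)).data
        return out[0] if squeeze else out

    def parameters(self):
        return self.net.parameters()


def build_generator(spec: GeneratorSpec | None = None,
                    seed: int = 0) -> GeneratorFunction:
    return GeneratorFunction(spec or GeneratorSpec(), seed=seed)


def build_discriminator(spec: DiscriminatorSpec | None = None,
                        seed: int = 0) -> DiscriminatorFunction:
    return DiscriminatorFunction(spec or DiscriminatorSpec(), seed=seed)
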