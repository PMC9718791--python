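"""Generator loss components: adversarial + 10 x [L1 + (1 - SSIM)].

The generator objective used by both translation stages is

    L_G = L_adv + lambda * [ (1/N) sum_i |G(M_i) - K_i|  +  (1 - SSIM(G(M), K)) ]

with lambda = 10, where M is the low-contrast (MV) input, K the kV target and
G the generator. SSIM follows the standard luminance/contrast/structure form

    SSIM(x, y) = (2 mu_x mu_y + c1)(2 cov_xy + c2)
                 / ((mu_x^2 + mu_y^2 + c1)(var_x + var_y + c2))

computed, by default, as the mean of local Gaussian-windowed statistics
(11x11 window, sigma 1.5, K1 = 0.01, K2 = 0.03 over the [-1, 1] data range of
normalized images); a ``global`` single-window mode with whole-image moments
is exposed for closed-form checks. The adversarial term is the conventional
non-saturating GAN binary cross-entropy; a least-squares variant is available
behind a flag.

Two parallel surfaces live here: plain-numpy functions (metrics, logging,
oracle tests) and ``*_t`` functions on autograd Tensors used inside the
training loop. Both implement the same formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .nn import autograd as ag
from .nn.autograd import Tensor

_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Weights and constants of the composite generator loss."""

    lambda_recon: float = 10.0
    adv_weight: float = 1.0
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    data_range: float = 2.0      # normalized images live in [-1, 1]
    ssim_window: int = 11
    ssim_sigma: float = 1.5
    ssim_mode: str = "windowed"  # "windowed" | "global"
    adversarial: str = "bce"     # "bce" | "lsgan"

    def __post_init__(self):
        if self.lambda_recon < 0:
            raise ValueError("lambda_recon must be >= 0")
        if self.ssim_mode not in ("windowed", "global"):
            raise ValueError(f"unknown ssim_mode {self.ssim_mode!r}")
        if self.adversarial not in ("bce", "lsgan"):
            raise ValueError(f"unknown adversarial kind {self.adversarial!r}")

    @property
    def c1(self) -> float:
        return (self.ssim_k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.ssim_k2 * self.data_range) ** 2


@dataclass
class LossBreakdown:
    """Per-batch components of the generator objective."""

    adversarial: float
    l1: float
    ssim: float
    total: float

    @classmethod
    def from_components(cls, adv: float, l1: float, ssim_val: float,
                        weights: LossWeights) -> "LossBreakdown":
        return cls(adversarial=float(adv), l1=float(l1), ssim=float(ssim_val),
                   total=generator_total(adv, l1, ssim_val, weights))


# ---------------------------------------------------------------------------
# numpy surface
# ---------------------------------------------------------------------------

def _check_same_shape(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def ssim(x: np.ndarray, y: np.ndarray,
         weights: LossWeights | None = None) -> float:
    """Structural similarity of two equally shaped 2D images.

    Windowed mode averages the SSIM map over the region where the full
    Gaussian window fits; global mode evaluates the formula once with
    whole-image moments (population normalization).
    """
    weights = weights or LossWeights()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_same_shape(x, y)
    c1, c2 = weights.c1, weights.c2
    if weights.ssim_mode == "global":
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = ((x - mx) * (y - my)).mean()
        return float((2 * mx * my + c1) * (2 * cov + c2)
                     / ((mx * mx + my * my + c1) * (vx + vy + c2)))
    sigma, win = weights.ssim_sigma, weights.ssim_window
    if min(x.shape) < win:
        raise ValueError(
            f"image {x.shape} smaller than the {win}x{win} SSIM window; "
            "use ssim_mode='global' for tiny images")
    truncate = ((win - 1) / 2) / sigma
    blur = lambda im: gaussian_filter(im, sigma, truncate=truncate)
    mx, my = blur(x), blur(y)
    vx = blur(x * x) - mx * mx
    vy = blur(y * y) - my * my
    cov = blur(x * y) - mx * my
    smap = ((2 * mx * my + c1) * (2 * cov + c2)
            / ((mx * mx + my * my + c1) * (vx + vy + c2)))
    pad = (win - 1) // 2
    return float(smap[pad:smap.shape[0] - pad, pad:smap.shape[1] - pad].mean())


def l1_term(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute difference (1/N) sum |pred_i - target_i|."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    _check_same_shape(pred, target)
    return float(np.abs(pred - target).mean())


def generator_total(adv: float, l1: float, ssim_val: float,
                    weights: LossWeights | None = None) -> float:
    weights = weights or LossWeights()
    return float(weights.adv_weight * adv
                 + weights.lambda_recon * (l1 + (1.0 - ssim_val)))


def adversarial_losses(d_real: np.ndarray, d_fake: np.ndarray,
                       kind: str = "bce") -> tuple[float, float]:
    """(generator_adv, discriminator_loss) from realness scores in (0, 1).

    BCE: the discriminator minimizes -[E log D(real) + E log(1 - D(fake))];
    the generator uses the non-saturating -E log D(fake). Scores are clamped
    away from {0, 1} so both losses stay finite. The least-squares variant
    uses (D - 1)^2 / D^2 targets instead.
    """
    d_real = np.clip(np.asarray(d_real, dtype=np.float64), _EPS, 1 - _EPS)
    d_fake = np.clip(np.asarray(d_fake, dtype=np.float64), _EPS, 1 - _EPS)
    if kind == "bce":
        disc = -(np.log(d_real).mean() + np.log1p(-d_fake).mean())
        gen = -np.log(d_fake).mean()
    elif kind == "lsgan":
        disc = ((d_real - 1.0) ** 2).mean() + (d_fake ** 2).mean()
        gen = ((d_fake - 1.0) ** 2).mean()
    else:
        raise ValueError(f"unknown adversarial kind {kind!r}")
    return float(gen), float(disc)


# ---------------------------------------------------------------------------
# autograd surface (training)
# ---------------------------------------------------------------------------

def _gaussian_kernel2d(win: int, sigma: float) -> np.ndarray:
    r = (win - 1) // 2
    ax = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    g /= g.sum()
    return np.outer(g, g)


def ssim_t(x: Tensor, y: Tensor, weights: LossWeights | None = None) -> Tensor:
    """SSIM of (N,1,H,W) Tensor batches; differentiable, mean over batch."""
    weights = weights or LossWeights()
    c1, c2 = weights.c1, weights.c2
    if weights.ssim_mode == "global":
        mx = ag.mean(x, axis=(2, 3), keepdims=True)
        my = ag.mean(y, axis=(2, 3), keepdims=True)
        vx = ag.mean(x * x, axis=(2, 3), keepdims=True) - mx * mx
        vy = ag.mean(y * y, axis=(2, 3), keepdims=True) - my * my
        cov = ag.mean(x * y, axis=(2, 3), keepdims=True) - mx * my
        s = ((mx * my * 2.0 + c1) * (cov * 2.0 + c2)
             / ((mx * mx + my * my + c1) * (vx + vy + c2)))
        return ag.mean(s)
    kernel = Tensor(_gaussian_kernel2d(weights.ssim_window,
                                       weights.ssim_sigma)[None, None])
    blur = lambda im: ag.conv2d(im, kernel)  # valid region only
    mx, my = blur(x), blur(y)
    vx = blur(x * x) - mx * mx
    vy = blur(y * y) - my * my
    cov = blur(x * y) - mx * my
    smap = ((mx * my * 2.0 + c1) * (cov * 2.0 + c2)
            / ((mx * mx + my * my + c1) * (vx + vy + c2)))
    return ag.mean(smap)


def l1_t(pred: Tensor, target: Tensor) -> Tensor:
    return ag.mean(ag.absolute(pred - target))


def generator_total_t(adv: Tensor, l1: Tensor, ssim_val: Tensor,
                      weights: LossWeights) -> Tensor:
    return (adv * weights.adv_weight
            + (l1 + (1.0 - ssim_val)) * weights.lambda_recon)


def adversarial_losses_t(d_real: Tensor, d_fake: Tensor,
                         kind: str = "bce") -> tuple[Tensor, Tensor]:
    d_real = ag.clip(d_real, _EPS, 1 - _EPS)
    d_fake = ag.clip(d_fake, _EPS, 1 - _EPS)
    if kind == "bce":
        disc = -(ag.mean(ag.log(d_real)) + ag.mean(ag.log(1.0 - d_fake)))
        gen = -ag.mean(ag.log(d_fake))
    elif kind == "lsgan":
        disc = ag.mean((d_real - 1.0) ** 2.0) + ag.mean(d_fake ** 2.0)
        gen = ag.mean((d_fake - 1.0) ** 2.0)
    else:
        raise ValueError(f"unknown adversarial kind {kind!r}")
    return gen, disc
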