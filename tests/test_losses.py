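"""Composite generator loss: brute-force oracles and closed-form checks."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from martian import losses as L
from martian.nn.autograd import Tensor


@pytest.fixture()
def random_pair(rng):
    x = rng.uniform(-1.0, 1.0, (8, 8))
    y = np.clip(x + rng.normal(0.0, 0.3, (8, 8)), -1.0, 1.0)
    return x, y


def brute_force_global_ssim(x, y, c1, c2):
    """Single-window SSIM evaluated directly from whole-image moments."""
    mx, my = x.mean(), y.mean()
    vx = ((x - mx) ** 2).mean()
    vy = ((y - my) ** 2).mean()
    cov = ((x - mx) * (y - my)).mean()
    return ((2 * mx * my + c1) * (2 * cov + c2)
            / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))


class TestSSIM:
    def test_identical_images_give_one(self, rng):
        x = rng.uniform(-1, 1, (16, 16))
        assert L.ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_global_mode_matches_brute_force(self, random_pair):
        x, y = random_pair
        w = L.LossWeights(ssim_mode="global")
        assert L.ssim(x, y, w) == pytest.approx(
            brute_force_global_ssim(x, y, w.c1, w.c2), abs=1e-6)

    def test_windowed_mode_matches_skimage(self, rng):
        x = rng.uniform(-1, 1, (32, 32))
        y = np.clip(x + rng.normal(0, 0.2, (32, 32)), -1, 1)
        ref = structural_similarity(x, y, data_range=2.0,
                                    gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False)
        assert L.ssim(x, y) == pytest.approx(ref, abs=1e-6)

    def test_constant_images_closed_form(self):
        # x = 1, y = 0, zero variance: value reduces to c1 / (1 + c1)
        x, y = np.ones((16, 16)), np.zeros((16, 16))
        w = L.LossWeights(ssim_mode="global")
        expected = w.c1 / (1.0 + w.c1)  # = 3.9984e-4 for c1 = (0.01*2)^2
        assert L.ssim(x, y, w) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(3.998e-4, abs=1e-6)

    def test_symmetry(self, rng, random_pair):
        x8, y8 = random_pair
        w = L.LossWeights(ssim_mode="global")
        assert L.ssim(x8, y8, w) == pytest.approx(L.ssim(y8, x8, w), abs=1e-12)
        x = rng.uniform(-1, 1, (16, 16))
        y = rng.uniform(-1, 1, (16, 16))
        assert L.ssim(x, y) == pytest.approx(L.ssim(y, x), abs=1e-12)

    def test_window_larger_than_image_rejected(self, random_pair):
        x, y = random_pair  # 8x8 < 11x11 window
        with pytest.raises(ValueError, match="global"):
            L.ssim(x, y)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            L.ssim(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_tensor_version_agrees_with_numpy(self, rng):
        x = rng.uniform(-1, 1, (2, 1, 32, 32))
        y = rng.uniform(-1, 1, (2, 1, 32, 32))
        per_image = np.mean([L.ssim(x[i, 0], y[i, 0]) for i in range(2)])
        batched = float(L.ssim_t(Tensor(x), Tensor(y)).data)
        assert batched == pytest.approx(per_image, abs=1e-5)


class TestL1:
    def test_identical_zero_and_constant_offset(self, rng):
        x = rng.uniform(-1, 1, (8, 8))
        assert L.l1_term(x, x) == 0.0
        assert L.l1_term(x + 0.1, x) == pytest.approx(0.1, abs=1e-12)

    def test_matches_loop_oracle(self, random_pair):
        x, y = random_pair
        expected = sum(abs(x[i, j] - y[i, j]) for i in range(8)
                       for j in range(8)) / 64.0
        assert L.l1_term(x, y) == pytest.approx(expected, abs=1e-10)


class TestGeneratorTotal:
    def test_printed_arithmetic(self):
        # adv 0.7, l1 0.05, ssim 0.9 -> 0.7 + 10 * (0.05 + 0.1) = 2.2
        assert L.generator_total(0.7, 0.05, 0.9) == pytest.approx(2.2)

    def test_perfect_reconstruction_leaves_adversarial(self):
        assert L.generator_total(0.31, 0.0, 1.0) == pytest.approx(0.31)

    def test_zero_lambda_degenerates_to_adversarial(self):
        w = L.LossWeights(lambda_recon=0.0)
        assert L.generator_total(0.42, 0.8, 0.1, w) == pytest.approx(0.42)

    def test_monotone_in_ssim_and_l1(self):
        ssims = np.linspace(0.1, 1.0, 7)
        totals = [L.generator_total(0.5, 0.05, s) for s in ssims]
        assert all(a >= b for a, b in zip(totals, totals[1:]))
        l1s = np.linspace(0.0, 0.5, 7)
        totals = [L.generator_total(0.5, v, 0.9) for v in l1s]
        assert all(a <= b for a, b in zip(totals, totals[1:]))


class TestAdversarial:
    def test_balanced_scores_closed_form(self):
        # D(real) = D(fake) = 0.5: disc loss = -(ln .5 + ln .5) = 2 ln 2
        gen, disc = L.adversarial_losses(np.array([0.5]), np.array([0.5]))
        assert disc == pytest.approx(2 * np.log(2), abs=1e-12)
        assert gen == pytest.approx(np.log(2), abs=1e-12)

    def test_confident_fake_drives_generator_loss_to_zero(self):
        gen, _ = L.adversarial_losses(np.array([0.5]), np.array([1.0 - 1e-9]))
        assert gen == pytest.approx(0.0, abs=1e-5)

    def test_extreme_scores_stay_finite(self):
        gen, disc = L.adversarial_losses(np.array([1e-7, 1 - 1e-7]),
                                         np.array([1e-7, 1 - 1e-7]))
        assert np.isfinite(gen) and np.isfinite(disc)
        gen, disc = L.adversarial_losses(np.array([0.0]), np.array([1.0]))
        assert np.isfinite(gen) and np.isfinite(disc)

    def test_lsgan_closed_form(self):
        gen, disc = L.adversarial_losses(np.array([0.8]), np.array([0.3]),
                                         kind="lsgan")
        assert disc == pytest.approx(0.04 + 0.09, abs=1e-12)
        assert gen == pytest.approx(0.49, abs=1e-12)

    def test_tensor_version_agrees(self, rng):
        dr = rng.uniform(0.1, 0.9, (5,))
        df = rng.uniform(0.1, 0.9, (5,))
        gen_np, disc_np = L.adversarial_losses(dr, df)
        gen_t, disc_t = L.adversarial_losses_t(Tensor(dr), Tensor(df))
        assert float(gen_t.data) == pytest.approx(gen_np, abs=1e-6)
        assert float(disc_t.data) == pytest.approx(disc_np, abs=1e-6)


def test_breakdown_satisfies_identity(rng):
    w = L.LossWeights()
    b = L.LossBreakdown.from_components(0.63, 0.08, 0.77, w)
    assert b.total == pytest.approx(
        b.adversarial + w.lambda_recon * (b.l1 + (1.0 - b.ssim)), abs=1e-12)
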