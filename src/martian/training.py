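"""Adversarial training of the two translation stages, plus inference.

Stage 1 learns MV -> kV modality translation on metal-free slice pairs
(target kV max <= 3000 HU, enforced at batch assembly); stage 2 learns
artifact-kV -> clean-kV correction on pairs manufactured by stage 1 plus
post-processing. Both use the same recipe: Adam (lr 2e-4, betas 0.5/0.999),
mini-batches of 3, alternating one discriminator step and one generator step
per batch, generator objective = adversarial + 10 x [L1 + (1 - SSIM)].

Everything is seeded and single-threaded-deterministic: two runs with the
same config produce identical loss trajectories.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from . import losses as L
from .io_prep import (METAL_THRESHOLD_HU, CTVolume, NormalizationWindow,
                      PairedSlice, denormalize, normalize)
from .networks import (DiscriminatorFunction, DiscriminatorSpec,
                       GeneratorFunction, GeneratorSpec, build_discriminator,
                       build_generator)
from .nn.autograd import Tensor
from .nn.optim import Adam


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-4
    batch_size: int = 3
    epochs: int = 100
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0
    val_fraction: float = 0.2      # per-study validation split
    stage: int = 1                 # 1: MV->kV (metal-free only), 2: MAR

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")


@dataclass
class EpochRecord:
    epoch: int
    loss: L.LossBreakdown
    disc_loss: float
    val_ssim: float
    val_mae: float


@dataclass
class StageReport:
    stage: int
    epochs: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1
    checkpoint_path: str | None = None

    def write_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "adversarial", "l1", "ssim", "total",
                             "disc_loss", "val_ssim", "val_mae"])
            for r in self.epochs:
                writer.writerow([r.epoch, r.loss.adversarial, r.loss.l1,
                                 r.loss.ssim, r.loss.total, r.disc_loss,
                                 r.val_ssim, r.val_mae])


def _validate_pairs(pairs: list[PairedSlice], stage: int) -> None:
    if not pairs:
        raise ValueError("empty pair list")
    for p in pairs:
        lo = min(p.input.min(), p.target.min())
        hi = max(p.input.max(), p.target.max())
        if not p.normalized or lo < -1.0 - 1e-9 or hi > 1.0 + 1e-9:
            raise ValueError(
                "training pairs must be normalized to [-1, 1] "
                f"(study {p.study_id}, slice {p.slice_index})")
        if stage == 1 and p.kv_max_hu > METAL_THRESHOLD_HU:
            raise ValueError(
                f"stage-1 pair {p.study_id}/{p.slice_index} has kV max "
                f"{p.kv_max_hu:.0f} HU > {METAL_THRESHOLD_HU:.0f}: metal "
                "slices are excluded from stage-1 training")


def split_by_study(pairs: list[PairedSlice], val_fraction: float,
                   seed: int) -> tuple[list[PairedSlice], list[PairedSlice]]:
    """Deterministic per-study train/validation split (no slice leakage)."""
    studies = sorted({p.study_id for p in pairs})
    rng = np.random.default_rng(seed)
    rng.shuffle(studies)
    n_val = max(1, int(round(len(studies) * val_fraction))) \
        if len(studies) > 1 else 0
    val_ids = set(studies[:n_val])
    train = [p for p in pairs if p.study_id not in val_ids]
    val = [p for p in pairs if p.study_id in val_ids]
    return (train, val) if train else (val, [])


def _assert_stage1_batch(batch: list[PairedSlice]) -> None:
    for p in batch:
        assert p.kv_max_hu <= METAL_THRESHOLD_HU, (
            f"stage-1 batch contains metal slice {p.study_id}/{p.slice_index}")


def _batch_arrays(batch: list[PairedSlice]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.input for p in batch])[:, None]
    y = np.stack([p.target for p in batch])[:, None]
    return x, y


def evaluate_pairs(gen: GeneratorFunction, pairs: list[PairedSlice],
                   weights: L.LossWeights) -> tuple[float, float]:
    """(mean SSIM, mean MAE) of G(input) vs target in normalized units."""
    if not pairs:
        return float("nan"), float("nan")
    ssims, maes = [], []
    for p in pairs:
        pred = gen(p.input)
        ssims.append(L.ssim(pred, p.target, weights))
        maes.append(L.l1_term(pred, p.target))
    return float(np.mean(ssims)), float(np.mean(maes))


def train_stage(pairs: list[PairedSlice], config: TrainConfig,
                weights: L.LossWeights | None = None,
                gen_spec: GeneratorSpec | None = None,
                disc_spec: DiscriminatorSpec | None = None,
                checkpoint_dir: str | None = None,
                val_studies: set[str] | None = None,
                ) -> tuple[GeneratorFunction, StageReport]:
    """Train one translation stage; returns the best-validation-SSIM model.

    The train/validation split is per study (``val_studies`` pins it
    explicitly, e.g. to keep stage-2 training disjoint from stage-1
    validation). All epochs' metrics are retained in the report so the
    checkpoint choice is auditable; if no validation studies exist the final
    epoch is used.
    """
    weights = weights or L.LossWeights()
    _validate_pairs(pairs, config.stage)
    if val_studies is not None:
        train = [p for p in pairs if p.study_id not in val_studies]
        val = [p for p in pairs if p.study_id in val_studies]
        if not train:
            raise ValueError("val_studies leaves no training pairs")
    else:
        train, val = split_by_study(pairs, config.val_fraction, config.seed)

    gen = build_generator(gen_spec, seed=config.seed)
    disc = build_discriminator(disc_spec, seed=config.seed + 1)
    opt_g = Adam(gen.parameters(), lr=config.learning_rate,
                 beta1=config.beta1, beta2=config.beta2)
    opt_d = Adam(disc.parameters(), lr=config.learning_rate,
                 beta1=config.beta1, beta2=config.beta2)
    rng = np.random.default_rng(config.seed)
    report = StageReport(stage=config.stage)
    best_ssim, best_state = -np.inf, None

    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        comp_log: list[tuple[float, float, float, float]] = []
        for start in range(0, len(train), config.batch_size):
            batch = [train[i] for i in order[start:start + config.batch_size]]
            if config.stage == 1:
                _assert_stage1_batch(batch)
            x, y = _batch_arrays(batch)

            # discriminator step (generator frozen: detached fake)
            fake = gen.forward_tensor(Tensor(x))
            d_real = disc.forward_tensor(Tensor(y))
            d_fake_detached = disc.forward_tensor(fake.detach())
            _, d_loss = L.adversarial_losses_t(d_real, d_fake_detached,
                                               weights.adversarial)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            # generator step (reuses the forward graph of `fake`)
            d_fake = disc.forward_tensor(fake)
            g_adv, _ = L.adversarial_losses_t(
                d_real.detach(), d_fake, weights.adversarial)
            l1 = L.l1_t(fake, Tensor(y))
            ssim_val = L.ssim_t(fake, Tensor(y), weights)
            g_total = L.generator_total_t(g_adv, l1, ssim_val, weights)
            opt_g.zero_grad()
            g_total.backward()
            opt_g.step()
            gen.step += 1
            comp_log.append((float(g_adv.data), float(l1.data),
                             float(ssim_val.data), float(d_loss.data)))

        adv_m, l1_m, ssim_m, d_m = (float(np.mean([c[i] for c in comp_log]))
                                    for i in range(4))
        val_ssim, val_mae = evaluate_pairs(gen, val, weights)
        report.epochs.append(EpochRecord(
            epoch=epoch,
            loss=L.LossBreakdown.from_components(adv_m, l1_m, ssim_m, weights),
            disc_loss=d_m, val_ssim=val_ssim, val_mae=val_mae))

        score = val_ssim if val else ssim_m
        if score >= best_ssim:
            best_ssim = score
            best_state = [a.copy() for a in gen.net.state_arrays()]
            report.best_epoch = epoch

    if best_state is not None:
        gen.net.load_state_arrays(best_state)
    if checkpoint_dir:
        os.makedirs(checkpoint_dir, exist_ok=True)
        path = os.path.join(checkpoint_dir, f"stage{config.stage}_best.npz")
        gen.save(path)
        report.checkpoint_path = path
        report.write_csv(os.path.join(checkpoint_dir,
                                      f"stage{config.stage}_log.csv"))
    return gen, report


def infer_volume(gen: GeneratorFunction, volume: CTVolume,
                 window: NormalizationWindow | None = None) -> CTVolume:
    """Run the generator slice-wise over a volume in HU.

    Every slice is mapped, including slices that were excluded from training
    by the metal rule; output is denormalized back to HU and tagged
    synthetic-kV.
    """
    window = window or NormalizationWindow()
    out = np.empty_like(volume.voxels)
    for k in range(volume.n_slices):
        pred = gen(normalize(volume.slice_at(k), window))
        out[:, :, k] = denormalize(pred, window)
    return CTVolume(voxels=out, grid=volume.grid, modality="synthetic-kV")
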