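"""Training-loop contracts at miniature scale: convergence, determinism,
the stage-1 metal exclusion, and slice-wise volume inference."""

import numpy as np
import pytest

from martian import losses as L
from martian.io_prep import (CTVolume, NormalizationWindow, PairedSlice,
                             VolumeGrid, normalize)
from martian.networks import DiscriminatorSpec, GeneratorSpec
from martian.training import (TrainConfig, evaluate_pairs, infer_volume,
                              split_by_study, train_stage)

GEN = GeneratorSpec(base_channels=4, n_residual=2)
DISC = DiscriminatorSpec(n_down=3, base_channels=4)


def make_pairs(rng, n=8, size=16, identical=False, max_hu=200.0):
    pairs = []
    for i in range(n):
        target = rng.uniform(-1, 1, (size, size)) * 0.5
        inp = target if identical else np.clip(
            target + rng.normal(0, 0.2, (size, size)), -1, 1)
        pairs.append(PairedSlice(input=inp.copy(), target=target.copy(),
                                 study_id=f"s{i % 4}", slice_index=i,
                                 kv_max_hu=max_hu, normalized=True))
    return pairs


class TestTrainStage:
    def test_autoencoding_run_halves_l1(self):
        """Identical-pair phantom slices with the adversarial term off: the
        generator is a pure autoencoder and its L1 must drop >= 50% in 5
        epochs."""
        from martian import phantom_sim as sim
        from martian.io_prep import normalize
        params = sim.DatasetParams(image_size=32, n_slices=2,
                                   metal_fraction=0.0)
        studies = sim.generate_dataset(10, params, seed=7)
        pairs = []
        for _ in range(3):  # repeats give the short run enough batches
            for s in studies:
                for k in range(s.n_slices):
                    t = normalize(s.kv_clean[k].pixels)
                    pairs.append(PairedSlice(
                        input=t.copy(), target=t.copy(),
                        study_id=s.study_id, slice_index=k,
                        kv_max_hu=200.0, normalized=True))
        weights = L.LossWeights(adv_weight=0.0)
        _, report = train_stage(
            pairs, TrainConfig(epochs=5, seed=0, val_fraction=0.0, stage=1),
            weights=weights,
            gen_spec=GeneratorSpec(base_channels=8, n_residual=2),
            disc_spec=DISC)
        first = report.epochs[0].loss.l1
        last = report.epochs[-1].loss.l1
        assert last <= 0.5 * first

    def test_same_seed_reproduces_epoch_losses(self, rng):
        pairs = make_pairs(rng, n=6)
        results = []
        for _ in range(2):
            _, report = train_stage(
                pairs, TrainConfig(epochs=1, seed=3, stage=1),
                gen_spec=GEN, disc_spec=DISC)
            r = report.epochs[0]
            results.append((r.loss.adversarial, r.loss.l1, r.loss.ssim,
                            r.loss.total, r.disc_loss))
        assert results[0] == results[1]

    def test_stage1_rejects_metal_slices(self, rng):
        pairs = make_pairs(rng, n=4, max_hu=3200.0)
        with pytest.raises(ValueError, match="excluded from stage-1"):
            train_stage(pairs, TrainConfig(epochs=1, seed=0, stage=1),
                        gen_spec=GEN, disc_spec=DISC)

    def test_stage2_accepts_metal_slices(self, rng):
        pairs = make_pairs(rng, n=6, max_hu=3200.0)
        _, report = train_stage(pairs, TrainConfig(epochs=1, seed=0, stage=2),
                                gen_spec=GEN, disc_spec=DISC)
        assert len(report.epochs) == 1

    def test_unnormalized_pairs_rejected(self, rng):
        bad = [PairedSlice(input=rng.uniform(-1000, 1000, (16, 16)),
                           target=rng.uniform(-1000, 1000, (16, 16)),
                           study_id="s", slice_index=0, kv_max_hu=100.0)]
        with pytest.raises(ValueError, match="normalized"):
            train_stage(bad, TrainConfig(epochs=1, seed=0),
                        gen_spec=GEN, disc_spec=DISC)

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_stage([], TrainConfig(epochs=1, seed=0),
                        gen_spec=GEN, disc_spec=DISC)

    def test_loss_breakdown_identity_every_epoch(self, rng):
        pairs = make_pairs(rng, n=6)
        weights = L.LossWeights()
        _, report = train_stage(pairs, TrainConfig(epochs=2, seed=1, stage=1),
                                weights=weights, gen_spec=GEN, disc_spec=DISC)
        for r in report.epochs:
            assert r.loss.total == pytest.approx(
                r.loss.adversarial + weights.lambda_recon
                * (r.loss.l1 + (1.0 - r.loss.ssim)), rel=1e-9)

    def test_checkpoint_written_and_loadable(self, rng, tmp_path):
        from martian.networks import GeneratorFunction
        pairs = make_pairs(rng, n=6)
        gen, report = train_stage(
            pairs, TrainConfig(epochs=1, seed=0, stage=1),
            gen_spec=GEN, disc_spec=DISC, checkpoint_dir=str(tmp_path))
        assert report.checkpoint_path is not None
        loaded = GeneratorFunction.load(report.checkpoint_path)
        x = pairs[0].input
        np.testing.assert_array_equal(loaded(x), gen(x))


class TestSplit:
    def test_split_is_per_study_and_disjoint(self, rng):
        pairs = make_pairs(rng, n=12)
        train, val = split_by_study(pairs, val_fraction=0.25, seed=0)
        train_ids = {p.study_id for p in train}
        val_ids = {p.study_id for p in val}
        assert train_ids.isdisjoint(val_ids)
        assert len(train) + len(val) == 12

    def test_explicit_val_studies_enforced(self, rng):
        pairs = make_pairs(rng, n=8)
        _, report = train_stage(
            pairs, TrainConfig(epochs=1, seed=0, stage=1),
            gen_spec=GEN, disc_spec=DISC, val_studies={"s0"})
        assert np.isfinite(report.epochs[0].val_ssim)


class TestInferVolume:
    def make_volume(self, rng, n_slices, max_hu=500.0):
        vox = rng.uniform(-1000, 300, (16, 16, n_slices))
        vox[8, 8, :] = max_hu
        grid = VolumeGrid(spacing=(1, 1, 1), origin=(0, 0, 0),
                          size=(16, 16, n_slices))
        return CTVolume(voxels=vox, grid=grid, modality="kV")

    def trained_gen(self, rng):
        gen, _ = train_stage(make_pairs(rng, n=6),
                             TrainConfig(epochs=1, seed=0, stage=1),
                             gen_spec=GEN, disc_spec=DISC)
        return gen

    def test_single_slice_volume_maps_to_hu(self, rng):
        gen = self.trained_gen(rng)
        window = NormalizationWindow()
        out = infer_volume(gen, self.make_volume(rng, 1), window)
        assert out.voxels.shape == (16, 16, 1)
        assert out.modality == "synthetic-kV"
        assert out.voxels.min() >= window.hu_min
        assert out.voxels.max() <= window.hu_max

    def test_inference_is_deterministic(self, rng):
        gen = self.trained_gen(rng)
        vol = self.make_volume(rng, 3)
        a = infer_volume(gen, vol)
        b = infer_volume(gen, vol)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_metal_slices_are_inferred_too(self, rng):
        """Slices above the exclusion threshold still get synthetic output."""
        gen = self.trained_gen(rng)
        vol = self.make_volume(rng, 3, max_hu=5000.0)
        out = infer_volume(gen, vol)
        assert out.voxels.shape == vol.voxels.shape
        assert np.all(np.isfinite(out.voxels))
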