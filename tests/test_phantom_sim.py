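"""Phantom rendering, sinogram-domain corruption, MV derivation, datasets."""

import numpy as np
import pytest

from martian import phantom_sim as sim
from martian.io_prep import AIR_HU, METAL_THRESHOLD_HU
from martian.registration import DeformationField

FAST_ARTIFACT = sim.ArtifactParams(n_projection_angles=90)


class TestRenderAnatomy:
    def test_empty_spec_renders_uniform_air(self):
        spec = sim.PhantomSpec(image_size=32,
                               body=sim.BodySpec(
                                   shape=sim.Shape((0.5, 0.5), (0.0, 0.0))))
        img = sim.render_anatomy(sim.PhantomSpec(
            image_size=32, body=sim.BodySpec(
                shape=sim.Shape((0.5, 0.5), (0.001, 0.001)),
                hu_range=(-1000.0, -1000.0))))
        # effectively structureless: everything at the air baseline
        assert np.all(img == AIR_HU)

    def test_metal_insert_sets_image_maximum(self):
        spec = sim.PhantomSpec(image_size=64, metal_inserts=(
            sim.MetalSpec(center=(0.5, 0.45), radius=0.04, hu=3500.0),))
        assert sim.render_anatomy(spec).max() == 3500.0

    def test_same_seed_renders_identical_arrays(self, head_spec):
        a = sim.render_anatomy(head_spec)
        b = sim.render_anatomy(head_spec)
        np.testing.assert_array_equal(a, b)

    def test_tissues_respect_declared_ranges(self, head_spec, head_image):
        body = head_spec.body.shape.mask(64)
        lo, hi = head_spec.body.hu_range
        soft = head_image[body & (head_image < 500)]
        assert soft.min() >= lo - 1e-9 and soft.max() <= hi + 1e-9
        assert np.all(head_image[~body] == AIR_HU)

    def test_shape_outside_body_rejected(self):
        spec = sim.PhantomSpec(image_size=32, bone_structures=(
            sim.BoneSpec(shape=sim.Shape((0.05, 0.05), (0.04, 0.04))),))
        with pytest.raises(ValueError, match="outside the body"):
            sim.render_anatomy(spec)

    def test_metal_air_overlap_rejected(self):
        spec = sim.PhantomSpec(
            image_size=32,
            air_cavities=(sim.AirSpec(shape=sim.Shape((0.5, 0.5), (0.06, 0.06))),),
            metal_inserts=(sim.MetalSpec(center=(0.5, 0.5), radius=0.03),))
        with pytest.raises(ValueError, match="overlaps"):
            sim.render_anatomy(spec)

    def test_sub_3000_metal_rejected(self):
        with pytest.raises(ValueError, match=">= 3000"):
            sim.MetalSpec(center=(0.5, 0.5), radius=0.02, hu=2500.0)


class TestCorruption:
    def test_severity_zero_matches_fbp_roundtrip_oracle(self, head_image):
        params = sim.ArtifactParams(n_projection_angles=90, severity=0.0)
        out = sim.corrupt_with_metal_artifacts(head_image, params)
        oracle = sim.fbp_roundtrip(head_image, 90)
        bound = np.abs(oracle - head_image).mean()
        assert np.abs(out - head_image).mean() <= bound + 1e-9

    def test_artifact_band_variance_exceeds_off_band(self, metal_image, rng):
        out = sim.corrupt_with_metal_artifacts(metal_image, FAST_ARTIFACT, rng)
        diff = out - metal_image
        # inserts sit at y ~ 28-29 px: band through both, off-band below
        band = diff[:, 26:32]
        off = diff[:, 45:51]
        assert band.std() > off.std()

    def test_empty_scan_reconstructs_to_zero_attenuation(self):
        out = sim.corrupt_with_metal_artifacts(
            np.full((32, 32), AIR_HU), FAST_ARTIFACT)
        assert np.abs(out - AIR_HU).max() < 1e-6

    def test_severity_monotonic_in_nonmetal_tissue(self, metal_image):
        mask = ~sim.metal_mask(metal_image)
        maes = []
        for severity in (0.0, 0.5, 1.0):
            params = sim.ArtifactParams(n_projection_angles=90,
                                        severity=severity)
            out = sim.corrupt_with_metal_artifacts(
                metal_image, params, np.random.default_rng(0))
            maes.append(np.abs(out - metal_image)[mask].mean())
        assert maes[0] <= maes[1] <= maes[2]

    def test_metal_pixels_read_bright_after_corruption(self, metal_image, rng):
        out = sim.corrupt_with_metal_artifacts(metal_image, FAST_ARTIFACT, rng)
        assert out.max() > METAL_THRESHOLD_HU

    def test_nonfinite_sinogram_fails_loudly(self, metal_image):
        bad = metal_image.copy()
        params = sim.ArtifactParams(n_projection_angles=45,
                                    beam_hardening_coeffs=(np.inf,))
        with pytest.raises(FloatingPointError):
            sim.corrupt_with_metal_artifacts(bad, params)


class TestDeriveMvLike:
    def test_identity_settings_return_input(self, head_image):
        out = sim.derive_mv_like(head_image, contrast_compression=1.0,
                                 noise_sigma=0.0, misregistration=None)
        np.testing.assert_array_equal(out, head_image)

    def test_compression_halves_bone_distance_to_water(self, head_image):
        out = sim.derive_mv_like(head_image, contrast_compression=0.5,
                                 noise_sigma=0.0)
        bone = head_image > 500
        np.testing.assert_allclose(out[bone], head_image[bone] * 0.5)

    def test_metal_retained_unscaled(self, metal_image):
        out = sim.derive_mv_like(metal_image, contrast_compression=0.3,
                                 noise_sigma=0.0)
        metal = sim.metal_mask(metal_image)
        np.testing.assert_array_equal(out[metal], metal_image[metal])

    def test_known_translation_recovered_by_shift_search(self, head_image):
        d = np.zeros((2, 64, 64))
        d[1, :, :] = 5.0  # sample 5 px to the right: content moves left... or
        out = sim.derive_mv_like(head_image, 1.0, 0.0,
                                 DeformationField(displacement=d))
        # brute-force search over integer shifts for best match
        best, best_err = None, np.inf
        for s in range(-8, 9):
            shifted = np.roll(head_image, s, axis=1)
            err = np.abs(out[:, 10:54] - shifted[:, 10:54]).mean()
            if err < best_err:
                best, best_err = s, err
        assert best == -5  # pull-back by +5 shifts content 5 columns down

    def test_invalid_compression_rejected(self, head_image):
        with pytest.raises(ValueError):
            sim.derive_mv_like(head_image, contrast_compression=0.0)


class TestDataset:
    PARAMS = sim.DatasetParams(image_size=32, n_slices=2,
                               artifact=sim.ArtifactParams(
                                   n_projection_angles=60))

    def test_generation_is_deterministic(self):
        a = sim.generate_dataset(3, self.PARAMS, seed=9)
        b = sim.generate_dataset(3, self.PARAMS, seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.stack("kv_artifact"),
                                          sb.stack("kv_artifact"))
            np.testing.assert_array_equal(sa.stack("mv_like"),
                                          sb.stack("mv_like"))

    def test_zero_metal_fraction_keeps_all_slices_below_threshold(self):
        params = sim.DatasetParams(image_size=32, n_slices=2,
                                   metal_fraction=0.0)
        for study in sim.generate_dataset(4, params, seed=1):
            assert study.stack("kv_artifact").max() <= METAL_THRESHOLD_HU
            assert not study.has_metal

    def test_default_metal_fraction_yields_about_72_of_90(self):
        params = sim.DatasetParams(image_size=32, n_slices=1)
        studies = sim.generate_dataset(90, params, seed=4)
        n_metal = sum(s.has_metal for s in studies)
        # binomial(90, 0.8): mean 72, sd ~3.8
        assert 60 <= n_metal <= 84

    def test_clean_channel_conserves_metal_values(self):
        study = sim.generate_study("s", self.PARAMS, seed=11, force_metal=True)
        for rec, has_metal in zip(study.kv_clean, study.metal_flags):
            if has_metal:
                metal = rec.pixels >= METAL_THRESHOLD_HU
                assert metal.any()
                # rendered values, not FBP-processed: uniform per insert
                assert rec.pixels[metal].max() <= 6000.0
                assert np.isin(rec.pixels[metal],
                               np.unique(rec.pixels[metal])[:4]).all()

    def test_stacks_share_shape_and_alignment(self):
        study = sim.generate_study("s", self.PARAMS, seed=3)
        assert study.stack("kv_clean").shape == study.stack("mv_like").shape
        assert study.n_slices == 2

    def test_save_load_round_trip(self, tmp_path):
        studies = sim.generate_dataset(2, self.PARAMS, seed=5)
        manifest = sim.save_dataset(studies, str(tmp_path), self.PARAMS, 5)
        loaded = sim.load_dataset(manifest)
        assert [s.study_id for s in loaded] == [s.study_id for s in studies]
        np.testing.assert_allclose(loaded[0].stack("kv_clean"),
                                   studies[0].stack("kv_clean"), atol=1e-3)
        assert loaded[0].metal_flags == studies[0].metal_flags
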