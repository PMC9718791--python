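"""Synthetic paired-modality head phantom studies with metal artifacts.

Each generated study emulates one radiotherapy patient scanned twice:

* ``kv_clean`` — the ideal artifact-free kV slice stack (ground truth; in a
  clinic this image does not exist, which is the whole point of the method);
* ``kv_artifact`` — the measured kV stack, where slices containing metal are
  corrupted in the sinogram domain (beam hardening, trace noise, photon
  starvation) and reconstructed by filtered back-projection, producing
  streaks and dark bands;
* ``mv_like`` — a low-contrast artifact-free rendition of the same anatomy
  (soft-tissue/bone contrast compressed toward water, extra noise, metal
  retained without streaks), misaligned by a known smooth deformation that
  stands in for inter-modality registration error.

The phantoms are elliptical head sections with bone, air cavities and
optional metal inserts; they are a test fixture with controllable artifact
phenomenology, not a calibrated physics simulation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.transform import radon, iradon

from .io_prep import (AIR_HU, METAL_THRESHOLD_HU, CTVolume, SliceRecord,
                      VolumeGrid, extract_slices, write_nifti, read_nifti)
from .registration import DeformationField

MU_WATER = 0.0206  # attenuation per pixel unit assigned to 0 HU


# ---------------------------------------------------------------------------
# phantom description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Shape:
    """Ellipse (optionally annular) in fractional image coordinates."""

    center: tuple[float, float]
    radii: tuple[float, float]
    inner_radii: tuple[float, float] | None = None

    def mask(self, size: int) -> np.ndarray:
        ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        cx, cy = (c * size for c in self.center)
        rx, ry = (max(r * size, 0.5) for r in self.radii)
        outer = ((ii - cx) / rx) ** 2 + ((jj - cy) / ry) ** 2 <= 1.0
        if self.inner_radii is None:
            return outer
        irx, iry = (max(r * size, 0.25) for r in self.inner_radii)
        inner = ((ii - cx) / irx) ** 2 + ((jj - cy) / iry) ** 2 <= 1.0
        return outer & ~inner


@dataclass(frozen=True)
class BodySpec:
    shape: Shape = Shape(center=(0.5, 0.5), radii=(0.42, 0.36))
    hu_range: tuple[float, float] = (10.0, 70.0)


@dataclass(frozen=True)
class BoneSpec:
    shape: Shape
    hu_range: tuple[float, float] = (700.0, 1300.0)
    hu: float | None = None  # fixed value (e.g. per-patient); else drawn


@dataclass(frozen=True)
class AirSpec:
    shape: Shape


@dataclass(frozen=True)
class MetalSpec:
    center: tuple[float, float]
    radius: float
    hu: float = 3500.0

    def __post_init__(self):
        if self.hu < METAL_THRESHOLD_HU:
            raise ValueError("metal HU must be >= 3000")

    @property
    def shape(self) -> Shape:
        return Shape(center=self.center, radii=(self.radius, self.radius))


@dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 128
    body: BodySpec = BodySpec()
    bone_structures: tuple[BoneSpec, ...] = ()
    air_cavities: tuple[AirSpec, ...] = ()
    metal_inserts: tuple[MetalSpec, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class ArtifactParams:
    """Sinogram-domain corruption model.

    ``beam_hardening_coeffs`` (a1, a2, ...) define the polynomial deficit
    a1*p + a2*p^2 + ... subtracted from line integrals p crossing metal;
    noise and saturation act on the same metal-trace bins; everything scales
    linearly with ``severity`` in [0, 1].
    """

    n_projection_angles: int = 180
    beam_hardening_coeffs: tuple[float, ...] = (0.0, 0.25)
    metal_trace_noise_sigma: float = 0.08
    photon_starvation_threshold: float = 3.5
    severity: float = 1.0
    mu_water: float = MU_WATER

    def __post_init__(self):
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.n_projection_angles < 1:
            raise ValueError("need at least one projection angle")


@dataclass
class PairedStudy:
    """Three aligned-by-construction slice stacks plus misregistration truth."""

    study_id: str
    kv_clean: list[SliceRecord]
    kv_artifact: list[SliceRecord]
    mv_like: list[SliceRecord]
    deformation_truth: DeformationField
    metal_flags: list[bool]
    severe_flags: list[bool]
    seed: int

    def __post_init__(self):
        n = len(self.kv_clean)
        if not (len(self.kv_artifact) == len(self.mv_like) == n):
            raise ValueError("stacks must share slice count")
        shapes = {r.pixels.shape for stack in
                  (self.kv_clean, self.kv_artifact, self.mv_like)
                  for r in stack}
        if len(shapes) > 1:
            raise ValueError("stacks must share spatial shape")

    @property
    def n_slices(self) -> int:
        return len(self.kv_clean)

    @property
    def has_metal(self) -> bool:
        return any(self.metal_flags)

    def stack(self, which: str) -> np.ndarray:
        records = getattr(self, which)
        return np.stack([r.pixels for r in records], axis=2)

    def volume(self, which: str, modality: str) -> CTVolume:
        vox = self.stack(which)
        grid = VolumeGrid(spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                          size=vox.shape)
        return CTVolume(voxels=vox, grid=grid, modality=modality)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_anatomy(spec: PhantomSpec) -> np.ndarray:
    """Rasterize a phantom spec into a 2D HU image (deterministic per seed)."""
    size = spec.image_size
    rng = np.random.default_rng(spec.seed)
    body_mask = spec.body.shape.mask(size)

    image = np.full((size, size), AIR_HU)
    lo, hi = spec.body.hu_range
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), 2.0)
    scale = np.max(np.abs(texture)) or 1.0
    soft = (lo + hi) / 2.0 + texture / scale * (hi - lo) / 2.0
    image[body_mask] = np.clip(soft, lo, hi)[body_mask]

    def _check_inside(mask: np.ndarray, what: str) -> None:
        if np.any(mask & ~body_mask):
            raise ValueError(f"{what} extends outside the body ellipse")

    for bone in spec.bone_structures:
        mask = bone.shape.mask(size)
        _check_inside(mask, "bone structure")
        hu = bone.hu if bone.hu is not None else float(rng.uniform(*bone.hu_range))
        image[mask] = hu

    air_total = np.zeros((size, size), dtype=bool)
    for cavity in spec.air_cavities:
        mask = cavity.shape.mask(size)
        _check_inside(mask, "air cavity")
        air_total |= mask
        image[mask] = AIR_HU

    for metal in spec.metal_inserts:
        mask = metal.shape.mask(size)
        _check_inside(mask, "metal insert")
        if np.any(mask & air_total):
            raise ValueError("metal insert overlaps an air cavity")
        image[mask] = metal.hu

    return image


def metal_mask(image: np.ndarray,
               threshold: float = METAL_THRESHOLD_HU) -> np.ndarray:
    return np.asarray(image) >= threshold


# ---------------------------------------------------------------------------
# sinogram-domain corruption
# ---------------------------------------------------------------------------

def hu_to_mu(image: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    return np.clip(mu_water * (1.0 + np.asarray(image) / 1000.0), 0.0, None)


def mu_to_hu(mu: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    return 1000.0 * (np.asarray(mu) / mu_water - 1.0)


def fbp_roundtrip(image: np.ndarray, n_angles: int = 180,
                  mu_water: float = MU_WATER) -> np.ndarray:
    """Uncorrupted forward/back-projection of an HU image (error oracle)."""
    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    sino = radon(hu_to_mu(image, mu_water), theta=theta, circle=False)
    recon = iradon(sino, theta=theta, filter_name="ramp", circle=False,
                   output_size=image.shape[0])
    return mu_to_hu(recon, mu_water)


def corrupt_with_metal_artifacts(clean: np.ndarray, params: ArtifactParams,
                                 rng: np.random.Generator | None = None,
                                 ) -> np.ndarray:
    """Project, distort rays crossing metal, reconstruct.

    The metal trace is identified by forward-projecting the metal mask;
    only trace bins receive the beam-hardening deficit, Gaussian noise and
    photon-starvation saturation, all scaled by ``severity``. With severity 0
    (or no metal) the output is the plain FBP round trip of the input.
    """
    rng = rng or np.random.default_rng(0)
    clean = np.asarray(clean, dtype=np.float64)
    theta = np.linspace(0.0, 180.0, params.n_projection_angles, endpoint=False)
    sino = radon(hu_to_mu(clean, params.mu_water), theta=theta, circle=False)

    mask = metal_mask(clean)
    if params.severity > 0 and mask.any():
        trace = radon(mask.astype(np.float64), theta=theta, circle=False) > 1e-6
        p = sino[trace]
        deficit = np.zeros_like(p)
        for k, a in enumerate(params.beam_hardening_coeffs, start=1):
            deficit += a * p ** k
        p = p - params.severity * deficit
        p = p + params.severity * rng.normal(
            0.0, params.metal_trace_noise_sigma, size=p.shape)
        excess = np.clip(p - params.photon_starvation_threshold, 0.0, None)
        p = p - params.severity * excess
        sino[trace] = p

    if not np.all(np.isfinite(sino)):
        raise FloatingPointError("non-finite sinogram values")
    recon = iradon(sino, theta=theta, filter_name="ramp", circle=False,
                   output_size=clean.shape[0])
    out = mu_to_hu(recon, params.mu_water)
    # the implant itself reads bright in a real scan (saturated detector
    # bins are interpolated around it, not through it): reinsert the metal
    # pixels so downstream >3000 HU masking behaves as it does clinically
    out[mask] = clean[mask]
    return out


# ---------------------------------------------------------------------------
# MV-like derivation
# ---------------------------------------------------------------------------

def random_deformation(shape: tuple[int, int], amplitude: float,
                       smoothness: float,
                       rng: np.random.Generator) -> DeformationField:
    """Smooth random displacement field with max magnitude ~ amplitude px."""
    d = rng.normal(0.0, 1.0, (2, *shape))
    d = np.stack([ndimage.gaussian_filter(c, smoothness) for c in d])
    peak = np.sqrt((d ** 2).sum(axis=0)).max() or 1.0
    return DeformationField(displacement=d / peak * amplitude)


def derive_mv_like(clean: np.ndarray, contrast_compression: float = 0.35,
                   noise_sigma: float = 25.0,
                   misregistration: DeformationField | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Low-contrast artifact-free rendition of a clean kV slice.

    Pixels above water (soft tissue, bone) are scaled toward 0 HU by the
    compression factor, emulating the loss of photoelectric contrast at
    megavoltage energies; metal keeps its HU (no streaks — that is the MV
    modality's defining property here); additive Gaussian noise; finally the
    stated misregistration field is applied and is the ground truth the
    multimodal registration stage is asked to recover.
    """
    if not 0.0 < contrast_compression <= 1.0:
        raise ValueError("contrast_compression must lie in (0, 1]")
    clean = np.asarray(clean, dtype=np.float64)
    out = clean.copy()
    compress = (clean > 0) & ~metal_mask(clean)
    out[compress] = clean[compress] * contrast_compression
    if noise_sigma > 0:
        rng = rng or np.random.default_rng(0)
        out = out + rng.normal(0.0, noise_sigma, out.shape)
    if misregistration is not None and \
            np.any(misregistration.displacement != 0.0):
        from .registration import apply_field
        out = apply_field(out, misregistration)
    return out


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetParams:
    """Study-level knobs of the synthetic cohort.

    Defaults mirror the modelled cohort: 80% of studies contain at least one
    metal-bearing slice, and a quarter of metal slices are dense objects
    without severe artifacts (the high-density, artifact-free category used
    in evaluation).
    """

    image_size: int = 128
    n_slices: int = 3
    metal_fraction: float = 0.8
    artifact_free_metal_fraction: float = 0.25
    artifact: ArtifactParams = ArtifactParams()
    contrast_compression: float = 0.35
    mv_noise_sigma: float = 25.0
    deformation_amplitude: float = 2.5
    deformation_smoothness: float = 8.0


@dataclass(frozen=True)
class _StudyAnatomy:
    """Patient-level anatomy; slices are jittered cross-sections of it.

    Shapes AND tissue intensities are study-level properties — one patient
    has one skull density and one soft-tissue baseline — while per-slice
    texture and shape jitter emulate the variation between adjacent
    cross-sections.
    """

    body_center: tuple[float, float]
    body_radii: tuple[float, float]
    tissue_hu: float
    skull_hu: float
    bone_blobs: tuple[tuple[tuple[float, float], tuple[float, float], float], ...]
    cavity: tuple[tuple[float, float], tuple[float, float]] | None
    metal_sites: tuple[tuple[tuple[float, float], float, float], ...]


def _random_anatomy(rng: np.random.Generator,
                    with_metal: bool) -> _StudyAnatomy:
    blobs = tuple(
        ((rng.uniform(0.38, 0.62), rng.uniform(0.38, 0.62)),
         (rng.uniform(0.03, 0.07), rng.uniform(0.03, 0.07)),
         float(rng.uniform(700.0, 1300.0)))
        for _ in range(rng.integers(1, 3)))
    cavity = None
    if rng.random() < 0.7:
        cavity = ((rng.uniform(0.42, 0.58), rng.uniform(0.55, 0.62)),
                  (rng.uniform(0.02, 0.05), rng.uniform(0.02, 0.05)))
    metals = tuple(
        ((rng.uniform(0.40, 0.60), rng.uniform(0.33, 0.44)),
         rng.uniform(0.02, 0.04), float(rng.uniform(3200.0, 6000.0)))
        for _ in range(rng.integers(1, 3))) if with_metal else ()
    return _StudyAnatomy(
        body_center=(0.5 + rng.uniform(-0.02, 0.02),
                     0.5 + rng.uniform(-0.02, 0.02)),
        body_radii=(rng.uniform(0.36, 0.42), rng.uniform(0.30, 0.36)),
        tissue_hu=float(rng.uniform(25.0, 55.0)),
        skull_hu=float(rng.uniform(800.0, 1200.0)),
        bone_blobs=blobs, cavity=cavity, metal_sites=metals)


def _slice_spec(anatomy: _StudyAnatomy, size: int,
                rng: np.random.Generator, slice_seed: int,
                with_metal: bool) -> PhantomSpec:
    """One axial cross-section: the study anatomy with small z-jitter."""
    def j(value: float, scale: float) -> float:
        return value + rng.uniform(-scale, scale)

    body = BodySpec(shape=Shape(
        center=(j(anatomy.body_center[0], 0.005),
                j(anatomy.body_center[1], 0.005)),
        radii=(j(anatomy.body_radii[0], 0.008),
               j(anatomy.body_radii[1], 0.008))),
        hu_range=(anatomy.tissue_hu - 20.0, anatomy.tissue_hu + 20.0))
    bones = [BoneSpec(shape=Shape(  # skull rim
        center=body.shape.center,
        radii=tuple(r * 0.92 for r in body.shape.radii),
        inner_radii=tuple(r * 0.80 for r in body.shape.radii)),
        hu=anatomy.skull_hu)]
    for center, radii, hu in anatomy.bone_blobs:
        bones.append(BoneSpec(shape=Shape(
            center=(j(center[0], 0.01), j(center[1], 0.01)),
            radii=(max(j(radii[0], 0.005), 0.01),
                   max(j(radii[1], 0.005), 0.01))), hu=hu))
    cavities = []
    if anatomy.cavity is not None:
        center, radii = anatomy.cavity
        cavities.append(AirSpec(shape=Shape(
            center=(j(center[0], 0.01), j(center[1], 0.01)),
            radii=(max(j(radii[0], 0.005), 0.01),
                   max(j(radii[1], 0.005), 0.01)))))
    metals: list[MetalSpec] = []
    if with_metal:
        for center, radius, hu in anatomy.metal_sites:
            metals.append(MetalSpec(
                center=(j(center[0], 0.005), j(center[1], 0.005)),
                radius=max(j(radius, 0.003), 0.015), hu=hu))
    return PhantomSpec(image_size=size, body=body,
                       bone_structures=tuple(bones),
                       air_cavities=tuple(cavities),
                       metal_inserts=tuple(metals),
                       seed=slice_seed)


def generate_study(study_id: str, params: DatasetParams, seed: int,
                   force_metal: bool | None = None) -> PairedStudy:
    rng = np.random.default_rng(seed)
    is_metal_study = (rng.random() < params.metal_fraction
                      if force_metal is None else force_metal)
    n = params.n_slices
    metal_slices = np.zeros(n, dtype=bool)
    if is_metal_study:
        k = int(rng.integers(1, n + 1))
        metal_slices[rng.choice(n, size=k, replace=False)] = True

    deformation = random_deformation(
        (params.image_size, params.image_size), params.deformation_amplitude,
        params.deformation_smoothness, rng)
    anatomy = _random_anatomy(rng, with_metal=is_metal_study)

    clean, artifact, mv = [], [], []
    severe_flags: list[bool] = []
    for k in range(n):
        slice_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = _slice_spec(anatomy, params.image_size, rng, slice_seed,
                           with_metal=bool(metal_slices[k]))
        img = render_anatomy(spec)
        severe = bool(metal_slices[k]
                      and rng.random() >= params.artifact_free_metal_fraction)
        if severe:
            art = corrupt_with_metal_artifacts(img, params.artifact, rng)
        else:
            art = img.copy()
        mvk = derive_mv_like(img, params.contrast_compression,
                             params.mv_noise_sigma, deformation, rng)
        clean.append(img)
        artifact.append(art)
        mv.append(mvk)
        severe_flags.append(severe)

    def _records(stack):
        return [SliceRecord(pixels=s, study_id=study_id, slice_index=i)
                for i, s in enumerate(stack)]

    return PairedStudy(study_id=study_id,
                       kv_clean=_records(clean),
                       kv_artifact=_records(artifact),
                       mv_like=_records(mv),
                       deformation_truth=deformation,
                       metal_flags=[bool(b) for b in metal_slices],
                       severe_flags=severe_flags,
                       seed=seed)


def generate_dataset(n_studies: int, params: DatasetParams | None = None,
                     seed: int = 0) -> list[PairedStudy]:
    """Generate mutually independent paired studies (deterministic per seed)."""
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    params = params or DatasetParams()
    root = np.random.default_rng(seed)
    study_seeds = root.integers(0, 2 ** 31 - 1, size=n_studies)
    return [generate_study(f"study{i:03d}", params, int(s))
            for i, s in enumerate(study_seeds)]


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def save_dataset(studies: list[PairedStudy], outdir: str,
                 params: DatasetParams | None = None, seed: int = 0) -> str:
    """One NIfTI per modality per study plus a JSON manifest; returns its path."""
    os.makedirs(outdir, exist_ok=True)
    manifest = {"seed": seed,
                "params": asdict(params) if params else None,
                "studies": []}
    for study in studies:
        entry = {"study_id": study.study_id, "seed": study.seed,
                 "metal_flags": study.metal_flags,
                 "severe_flags": study.severe_flags, "files": {}}
        for which, modality in (("kv_clean", "kV"), ("kv_artifact", "kV"),
                                ("mv_like", "MV")):
            path = os.path.join(outdir, f"{study.study_id}_{which}.nii")
            write_nifti(study.volume(which, modality), path)
            entry["files"][which] = os.path.basename(path)
        manifest["studies"].append(entry)
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def load_dataset(manifest_path: str) -> list[PairedStudy]:
    root = os.path.dirname(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    studies = []
    for entry in manifest["studies"]:
        stacks = {}
        for which in ("kv_clean", "kv_artifact", "mv_like"):
            vol = read_nifti(os.path.join(root, entry["files"][which]))
            stacks[which] = extract_slices(vol, entry["study_id"])
        shape = stacks["kv_clean"][0].pixels.shape
        studies.append(PairedStudy(
            study_id=entry["study_id"],
            kv_clean=stacks["kv_clean"],
            kv_artifact=stacks["kv_artifact"],
            mv_like=stacks["mv_like"],
            deformation_truth=DeformationField.zero(shape),
            metal_flags=entry["metal_flags"],
            severe_flags=entry["severe_flags"],
            seed=entry["seed"]))
    return studies
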