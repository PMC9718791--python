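"""Volume I/O and training-data preparation.

Covers the data plumbing around the two translation stages: reading DICOM
series / NIfTI volumes in Hounsfield units, resampling the kV volume onto the
MV grid, extracting axial slices and partitioning them by maximum HU (the
stage-1 exclusion rule: slices whose kV maximum exceeds 3000 HU carry metal
and are withheld from stage-1 training), affine normalization to the
network's [-1, 1] intensity range, and paired geometric augmentation
(left-right flip, small rotation, integer translation) applied identically
to both images of a training pair.

Conventions: voxel arrays are indexed (x, y, z) with axial slices along the
third axis; grids are axis-aligned, world = origin + index * spacing (mm);
voxel indices are 0-based. Out-of-field values are filled with -1000 HU (air).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

AIR_HU = -1000.0
METAL_THRESHOLD_HU = 3000.0

CATEGORY_METAL_FREE = "metal_free"
CATEGORY_METAL = "metal_containing"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned voxel lattice: spacing and origin in mm, size in voxels."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    size: tuple[int, int, int]

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if any(n < 1 for n in self.size):
            raise ValueError("size must be >= 1 per axis")

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.size) - 1) * np.asarray(self.spacing)
        return lo, hi


@dataclass
class CTVolume:
    """3D HU array with grid geometry and a modality tag."""

    voxels: np.ndarray
    grid: VolumeGrid
    modality: str = "kV"  # {"kV", "MV", "synthetic-kV"}

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D (x, y, z)")
        if tuple(self.voxels.shape) != tuple(self.grid.size):
            raise ValueError(
                f"voxel shape {self.voxels.shape} != grid size {self.grid.size}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite HU")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    def slice_at(self, k: int) -> np.ndarray:
        return self.voxels[:, :, k]


@dataclass
class SliceRecord:
    """One axial slice with provenance and its max-HU category."""

    pixels: np.ndarray
    study_id: str
    slice_index: int
    max_hu: float = field(init=False)
    category: str = field(init=False)
    threshold_hu: float = METAL_THRESHOLD_HU

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be 2D")
        self.max_hu = float(self.pixels.max())
        self.category = (CATEGORY_METAL if self.max_hu > self.threshold_hu
                         else CATEGORY_METAL_FREE)


@dataclass
class PairedSlice:
    """Aligned (input, target) slice pair for either training stage.

    ``kv_max_hu`` carries the maximum HU of the associated *true kV* slice,
    the quantity the stage-1 exclusion rule and the evaluation categories
    key on, even after the images themselves have been normalized.
    """

    input: np.ndarray
    target: np.ndarray
    study_id: str
    slice_index: int
    kv_max_hu: float
    normalized: bool = False

    def __post_init__(self):
        self.input = np.asarray(self.input, dtype=np.float64)
        self.target = np.asarray(self.target, dtype=np.float64)
        if self.input.shape != self.target.shape:
            raise ValueError("paired images must share shape")


@dataclass(frozen=True)
class NormalizationWindow:
    """HU window mapped affinely onto [-1, 1]; values outside are clipped.

    The default [-1024, 3071] covers the standard 12-bit CT range including
    dense implant material up to the 3000 HU exclusion threshold.
    """

    hu_min: float = -1024.0
    hu_max: float = 3071.0

    def __post_init__(self):
        if not self.hu_min < self.hu_max:
            raise ValueError("hu_min must be < hu_max")


@dataclass(frozen=True)
class AugmentationConfig:
    """Paired geometric augmentation ranges.

    flip_lr draws a fair coin; rotation is uniform in +-rotation_deg degrees;
    translation is an integer draw in +-translation_voxels per axis. One
    augmented copy per original for stage 1 ("doubling"), two for stage 2
    ("tripling").
    """

    flip_lr: bool = True
    rotation_deg: float = 10.0
    translation_voxels: int = 20
    copies_stage1: int = 1
    copies_stage2: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.rotation_deg < 0 or self.translation_voxels < 0:
            raise ValueError("augmentation ranges must be non-negative")


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

def write_nifti(volume: CTVolume, path: str) -> None:
    affine = np.diag(list(volume.grid.spacing) + [1.0])
    affine[:3, 3] = volume.grid.origin
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
    img.header["descrip"] = volume.modality.encode()[:79]
    nib.save(img, path)


def read_nifti(path: str, modality: str = "kV") -> CTVolume:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    affine = img.affine
    spacing = tuple(float(abs(affine[i, i])) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    grid = VolumeGrid(spacing=spacing, origin=origin, size=tuple(data.shape))
    return CTVolume(voxels=data, grid=grid, modality=modality)


def read_dicom_series(directory: str, modality: str = "kV") -> CTVolume:
    """Read an axial DICOM series; rescale slope/intercept applied."""
    files = [os.path.join(directory, f) for f in sorted(os.listdir(directory))
             if not f.startswith(".")]
    datasets = [pydicom.dcmread(f) for f in files]
    if not datasets:
        raise ValueError(f"no DICOM files in {directory}")
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr.T * slope + intercept)  # DICOM rows=y, cols=x
    voxels = np.stack(slices, axis=2)
    first = datasets[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    if len(datasets) > 1:
        dz = float(datasets[1].ImagePositionPatient[2]) - \
            float(datasets[0].ImagePositionPatient[2])
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    grid = VolumeGrid(spacing=(dx, dy, abs(dz)), origin=origin,
                      size=tuple(voxels.shape))
    return CTVolume(voxels=voxels, grid=grid, modality=modality)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_to_grid(moving: CTVolume, target: VolumeGrid,
                     interpolation: str = "linear") -> CTVolume:
    """Resample a volume onto a target grid by world-coordinate mapping.

    Linear interpolation for images, nearest for masks; voxels outside the
    moving field of view are filled with -1000 HU. Raises if the two fields
    of view do not overlap at all.
    """
    lo_m, hi_m = moving.grid.world_extent()
    lo_t, hi_t = target.world_extent()
    if np.any(hi_t < lo_m) or np.any(lo_t > hi_m):
        raise ValueError("moving and target fields of view are disjoint")
    idx = np.meshgrid(*[np.arange(n) for n in target.size], indexing="ij")
    coords = []
    for ax in range(3):
        world = target.origin[ax] + idx[ax] * target.spacing[ax]
        coords.append((world - moving.grid.origin[ax]) / moving.grid.spacing[ax])
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(moving.voxels, np.stack(coords), order=order,
                                  mode="constant", cval=AIR_HU)
    return CTVolume(voxels=out, grid=target, modality=moving.modality)


# ---------------------------------------------------------------------------
# slice partitioning
# ---------------------------------------------------------------------------

def extract_slices(volume: CTVolume, study_id: str,
                   threshold_hu: float = METAL_THRESHOLD_HU) -> list[SliceRecord]:
    return [SliceRecord(pixels=volume.slice_at(k), study_id=study_id,
                        slice_index=k, threshold_hu=threshold_hu)
            for k in range(volume.n_slices)]


def partition_slices(volume: CTVolume, threshold_hu: float = METAL_THRESHOLD_HU,
                     study_id: str = "study",
                     ) -> tuple[list[SliceRecord], list[SliceRecord]]:
    """Split axial slices into (included, excluded) by maximum HU.

    Included slices have max HU <= threshold (metal-free by the 3000 HU
    rule); excluded slices are the metal-containing remainder. Order is
    preserved and the two lists cover every slice exactly once.
    """
    if volume.n_slices < 1:
        raise ValueError("volume has no slices")
    records = extract_slices(volume, study_id, threshold_hu)
    included = [r for r in records if r.max_hu <= threshold_hu]
    excluded = [r for r in records if r.max_hu > threshold_hu]
    return included, excluded


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(image: np.ndarray,
              window: NormalizationWindow | None = None) -> np.ndarray:
    """Affine map of HU onto [-1, 1]; out-of-window values are clipped."""
    window = window or NormalizationWindow()
    image = np.asarray(image, dtype=np.float64)
    clipped = np.clip(image, window.hu_min, window.hu_max)
    return 2.0 * (clipped - window.hu_min) / (window.hu_max - window.hu_min) - 1.0


def denormalize(image: np.ndarray,
                window: NormalizationWindow | None = None) -> np.ndarray:
    window = window or NormalizationWindow()
    image = np.asarray(image, dtype=np.float64)
    return (image + 1.0) / 2.0 * (window.hu_max - window.hu_min) + window.hu_min


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Draw:
    flip: bool
    angle_deg: float
    shift: tuple[int, int]


def _sample_draw(config: AugmentationConfig, draw_seed: int) -> _Draw:
    rng = np.random.default_rng((config.seed, draw_seed))
    flip = bool(config.flip_lr and rng.integers(0, 2))
    angle = float(rng.uniform(-config.rotation_deg, config.rotation_deg)) \
        if config.rotation_deg > 0 else 0.0
    t = config.translation_voxels
    shift = (int(rng.integers(-t, t + 1)), int(rng.integers(-t, t + 1))) \
        if t > 0 else (0, 0)
    return _Draw(flip=flip, angle_deg=angle, shift=shift)


def _apply_draw(image: np.ndarray, draw: _Draw,
                fill: float = AIR_HU) -> np.ndarray:
    out = image
    if draw.flip:
        out = out[:, ::-1]
    if draw.angle_deg != 0.0:
        out = ndimage.rotate(out, draw.angle_deg, reshape=False, order=1,
                             mode="constant", cval=fill)
    if draw.shift != (0, 0):
        out = ndimage.shift(out, draw.shift, order=0, mode="constant",
                            cval=fill)
    return np.ascontiguousarray(out)


def augment(pair: PairedSlice, config: AugmentationConfig,
            draw_seed: int) -> PairedSlice:
    """Apply one sampled flip/rotation/translation to BOTH pair images.

    The transform is drawn from (config.seed, draw_seed) so a draw is
    reproducible; translation pads with -1000 HU and rotation uses linear
    interpolation.
    """
    draw = _sample_draw(config, draw_seed)
    fill = -1.0 if pair.normalized else AIR_HU
    return replace(pair,
                   input=_apply_draw(pair.input, draw, fill),
                   target=_apply_draw(pair.target, draw, fill))
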