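"""Rigid + cubic B-spline deformable registration (2D slices).

Two modes mirror the two places registration enters the pipeline:
``multimodal_MI`` (Mattes mutual information, 32 bins) aligns the MV image to
the kV image before stage-1 training, and ``monomodal_MSE`` (mean squared
error) refines the synthesized kV against the true kV after intensity
override. Both run a rigid stage first, then a cubic B-spline stage with a
three-level multiresolution schedule (coarse-to-fine control-point spacing).

SimpleITK provides the optimizer/transform machinery behind this module's
contract; displacement-field warping (`apply_field`) is a plain
scipy.ndimage resampling so fields from any source can be applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .io_prep import AIR_HU

MODE_MULTIMODAL = "multimodal_MI"
MODE_MONOMODAL = "monomodal_MSE"


@dataclass(frozen=True)
class RegistrationConfig:
    """Similarity metric, multiresolution schedule and iteration budget."""

    mode: str = MODE_MONOMODAL
    levels: int = 3
    bspline_grid_spacing: tuple[float, ...] = (64.0, 32.0, 16.0)  # mm/level
    rigid_first: bool = True
    max_iterations: int = 50
    mi_bins: int = 32
    rigid_only: bool = False

    def __post_init__(self):
        if self.mode not in (MODE_MULTIMODAL, MODE_MONOMODAL):
            raise ValueError(f"unknown registration mode {self.mode!r}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.bspline_grid_spacing) != self.levels:
            raise ValueError("one B-spline grid spacing per level required")
        if any(a <= b for a, b in zip(self.bspline_grid_spacing,
                                      self.bspline_grid_spacing[1:])):
            raise ValueError("grid spacing must decrease per level")


@dataclass
class DeformationField:
    """Dense per-pixel displacement, shape (2, H, W), in pixel units.

    displacement[0] moves along axis 0 (rows / x of the slice array),
    displacement[1] along axis 1. A point at index (i, j) of the fixed image
    samples the moving image at (i + d0[i,j], j + d1[i,j]).
    """

    displacement: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.ndim != 3 or self.displacement.shape[0] != 2:
            raise ValueError("displacement must have shape (2, H, W)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacement.shape[1:]

    def mean_magnitude(self) -> float:
        return float(np.sqrt((self.displacement ** 2).sum(axis=0)).mean())

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "DeformationField":
        return cls(displacement=np.zeros((2, *shape)))


@dataclass
class RegistrationResult:
    warped: np.ndarray
    field: DeformationField
    metric_trace: list[float]
    level_starts: list[int] = field(default_factory=list)
    degenerate: bool = False


def apply_field(image: np.ndarray, fld: DeformationField,
                fill: float = AIR_HU, order: int = 1) -> np.ndarray:
    """Warp an image by a dense displacement field (pull-back resampling)."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != fld.shape:
        raise ValueError(
            f"image shape {image.shape} != field grid {fld.shape}")
    ii, jj = np.meshgrid(np.arange(image.shape[0]), np.arange(image.shape[1]),
                         indexing="ij")
    coords = np.stack([ii + fld.displacement[0], jj + fld.displacement[1]])
    return ndimage.map_coordinates(image, coords, order=order,
                                   mode="constant", cval=fill)


def invert_field(fld: DeformationField, iterations: int = 20) -> DeformationField:
    """Fixed-point numerical inverse: d_inv(x) = -d(x + d_inv(x))."""
    d = fld.displacement
    inv = np.zeros_like(d)
    ii, jj = np.meshgrid(np.arange(d.shape[1]), np.arange(d.shape[2]),
                         indexing="ij")
    for _ in range(iterations):
        coords = np.stack([ii + inv[0], jj + inv[1]])
        inv = -np.stack([
            ndimage.map_coordinates(d[0], coords, order=1, mode="nearest"),
            ndimage.map_coordinates(d[1], coords, order=1, mode="nearest"),
        ])
    return DeformationField(displacement=inv, spacing=fld.spacing)


# ---------------------------------------------------------------------------
# SimpleITK-backed estimation
# ---------------------------------------------------------------------------

def _to_sitk(image: np.ndarray) -> sitk.Image:
    # numpy (x, y) -> sitk expects (y, x) ordering via GetImageFromArray
    return sitk.GetImageFromArray(np.ascontiguousarray(image.T).astype(np.float64))


def _set_metric(reg: sitk.ImageRegistrationMethod, config: RegistrationConfig):
    if config.mode == MODE_MULTIMODAL:
        reg.SetMetricAsMattesMutualInformation(
            numberOfHistogramBins=config.mi_bins)
    else:
        reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)


def _transform_to_field(transform: sitk.Transform,
                        shape: tuple[int, int]) -> DeformationField:
    ref = sitk.Image(int(shape[1]), int(shape[0]), sitk.sitkFloat64)
    filt = sitk.TransformToDisplacementFieldFilter()
    filt.SetReferenceImage(ref)
    disp = sitk.GetArrayFromImage(filt.Execute(transform))  # (x?, ...) -> (H,W,2)
    # array comes back as (rows=y, cols=x, [dx, dy]); convert to our (2, x, y)
    d = np.stack([disp[:, :, 0].T, disp[:, :, 1].T])
    return DeformationField(displacement=d)


def register(fixed: np.ndarray, moving: np.ndarray,
             config: RegistrationConfig | None = None) -> RegistrationResult:
    """Estimate the rigid + B-spline transform mapping `moving` onto `fixed`.

    Returns the warped moving image, the composed dense displacement field on
    the fixed grid (pixel units) and the per-iteration metric trace.
    Degenerate (constant) inputs yield the identity transform with a warning.
    """
    config = config or RegistrationConfig()
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape or fixed.ndim != 2:
        raise ValueError("fixed and moving must be equally shaped 2D images")
    if np.ptp(fixed) == 0 or np.ptp(moving) == 0:
        warnings.warn("degenerate (constant) image: returning identity",
                      stacklevel=2)
        return RegistrationResult(warped=moving.copy(),
                                  field=DeformationField.zero(fixed.shape),
                                  metric_trace=[], degenerate=True)

    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)
    trace: list[float] = []
    level_starts: list[int] = []
    composite = sitk.CompositeTransform(2)

    if config.rigid_first:
        reg = sitk.ImageRegistrationMethod()
        _set_metric(reg, config)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-4,
            numberOfIterations=config.max_iterations,
            relaxationFactor=0.6)
        reg.SetOptimizerScalesFromPhysicalShift()
        initial = sitk.CenteredTransformInitializer(
            f_img, m_img, sitk.Euler2DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY)
        reg.SetInitialTransform(initial, inPlace=True)
        shrink = [2 ** (config.levels - 1 - i) for i in range(config.levels)]
        reg.SetShrinkFactorsPerLevel(shrink)
        reg.SetSmoothingSigmasPerLevel([max(s - 1, 0) for s in shrink])
        reg.AddCommand(sitk.sitkIterationEvent,
                       lambda: trace.append(reg.GetMetricValue()))
        reg.AddCommand(sitk.sitkMultiResolutionIterationEvent,
                       lambda: level_starts.append(len(trace)))
        rigid = reg.Execute(f_img, m_img)
        composite.AddTransform(rigid)

    if not config.rigid_only:
        reg = sitk.ImageRegistrationMethod()
        _set_metric(reg, config)
        reg.SetOptimizerAsLBFGS2(
            numberOfIterations=config.max_iterations,
            deltaConvergenceTolerance=1e-7)
        if config.rigid_first:
            reg.SetMovingInitialTransform(composite)
        coarsest = config.bspline_grid_spacing[0]
        phys = [sz * sp for sz, sp in zip(f_img.GetSize(), f_img.GetSpacing())]
        mesh = [max(1, int(round(p / coarsest))) for p in phys]
        bspline = sitk.BSplineTransformInitializer(f_img, mesh, order=3)
        # scale factor 2 per level refines control-point spacing 64->32->16
        reg.SetInitialTransformAsBSpline(
            bspline, inPlace=True,
            scaleFactors=[2 ** i for i in range(config.levels)])
        shrink = [2 ** (config.levels - 1 - i) for i in range(config.levels)]
        reg.SetShrinkFactorsPerLevel(shrink)
        reg.SetSmoothingSigmasPerLevel([max(s - 1, 0) for s in shrink])
        reg.AddCommand(sitk.sitkIterationEvent,
                       lambda: trace.append(reg.GetMetricValue()))
        reg.AddCommand(sitk.sitkMultiResolutionIterationEvent,
                       lambda: level_starts.append(len(trace)))
        reg.Execute(f_img, m_img)
        composite.AddTransform(bspline)

    fld = _transform_to_field(composite, fixed.shape)
    warped = apply_field(moving, fld)
    return RegistrationResult(warped=warped, field=fld, metric_trace=trace,
                              level_starts=level_starts)
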