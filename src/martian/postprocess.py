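"""Post-processing chain turning stage-1 outputs into stage-2 targets.

The synthesized kV volume cannot depict metal (those slices were excluded
from stage-1 training), so two corrections are applied before it may serve
as a training target: (1) intensity override — voxels where the TRUE kV
exceeds the metal threshold are copied from the true kV into the synthetic
volume, so implants (but not their artifacts) are retained; (2) mono-modal
deformable refinement — the overridden synthetic volume is registered
slice-wise onto the true kV with an MSE metric to absorb residual
multimodal-registration error. Stage-2 pairs are then (true contaminated kV,
refined synthetic kV), restricted to studies that contain metal slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_prep import METAL_THRESHOLD_HU, CTVolume, PairedSlice
from .registration import (MODE_MONOMODAL, RegistrationConfig, register)


@dataclass(frozen=True)
class OverrideRule:
    """Voxels where the true kV exceeds `threshold_hu` overwrite the
    synthetic volume; the mask may be dilated to catch partial-volume rims."""

    threshold_hu: float = METAL_THRESHOLD_HU
    mask_dilation_voxels: int = 0


def _check_same_grid(a: CTVolume, b: CTVolume) -> None:
    if a.grid != b.grid:
        raise ValueError("volumes must share the same grid")
    if a.voxels.shape != b.voxels.shape:
        raise ValueError("volumes must share shape")


def override_mask(true_kv: CTVolume, rule: OverrideRule) -> np.ndarray:
    mask = true_kv.voxels > rule.threshold_hu
    if rule.mask_dilation_voxels > 0:
        mask = ndimage.binary_dilation(mask,
                                       iterations=rule.mask_dilation_voxels)
    return mask


def intensity_override(synthetic: CTVolume, true_kv: CTVolume,
                       rule: OverrideRule | None = None) -> CTVolume:
    """Copy high-intensity true-kV voxels into the synthetic volume.

    Idempotent; voxels outside the mask are bit-identical to the synthetic
    input.
    """
    rule = rule or OverrideRule()
    _check_same_grid(synthetic, true_kv)
    mask = override_mask(true_kv, rule)
    out = synthetic.voxels.copy()
    out[mask] = true_kv.voxels[mask]
    return CTVolume(voxels=out, grid=synthetic.grid,
                    modality=synthetic.modality)


def refine_monomodal(overridden: CTVolume, true_kv: CTVolume,
                     config: RegistrationConfig | None = None,
                     rule: OverrideRule | None = None) -> CTVolume:
    """Slice-wise MSE deformable refinement of the synthetic onto the true kV.

    After warping, the intensity override is re-applied so metal voxels are
    exactly preserved rather than smeared by interpolation.
    """
    config = config or RegistrationConfig(mode=MODE_MONOMODAL)
    if config.mode != MODE_MONOMODAL:
        raise ValueError("refinement requires monomodal_MSE registration")
    rule = rule or OverrideRule()
    _check_same_grid(overridden, true_kv)
    out = np.empty_like(overridden.voxels)
    for k in range(overridden.n_slices):
        result = register(true_kv.slice_at(k), overridden.slice_at(k), config)
        out[:, :, k] = result.warped
    refined = CTVolume(voxels=out, grid=overridden.grid,
                       modality=overridden.modality)
    return intensity_override(refined, true_kv, rule)


def build_stage2_pairs(true_kv_volumes: dict[str, CTVolume],
                       refined_volumes: dict[str, CTVolume],
                       threshold_hu: float = METAL_THRESHOLD_HU,
                       metal_slices_only: bool = False) -> list[PairedSlice]:
    """Pair (contaminated true kV, refined synthetic kV) slices for stage 2.

    Only studies containing at least one metal slice contribute; by default
    every slice of such a study is included (metal-free slices from metal
    studies add data), with a flag to restrict to metal slices only.
    """
    if set(true_kv_volumes) != set(refined_volumes):
        raise ValueError("study sets of the two volume dicts differ")
    pairs: list[PairedSlice] = []
    for study_id in sorted(true_kv_volumes):
        true_vol = true_kv_volumes[study_id]
        refined_vol = refined_volumes[study_id]
        _check_same_grid(true_vol, refined_vol)
        slice_max = true_vol.voxels.max(axis=(0, 1))
        if not np.any(slice_max > threshold_hu):
            continue
        for k in range(true_vol.n_slices):
            if metal_slices_only and slice_max[k] <= threshold_hu:
                continue
            pairs.append(PairedSlice(
                input=true_vol.slice_at(k),
                target=refined_vol.slice_at(k),
                study_id=study_id, slice_index=k,
                kv_max_hu=float(slice_max[k])))
    return pairs
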