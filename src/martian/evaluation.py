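"""Image-similarity reporting in HU: per-slice SSIM/MAE and summary tables.

Metrics are pure functions of their inputs. SSIM in evaluation space is
computed after windowing both images to a display range (default
[-1000, 1500] HU, the soft-tissue/bone window) and rescaling to [-1, 1], so
it is invariant to a joint affine HU rescaling applied consistently with the
window. Slices are bucketed as metal_free / metal_containing by a maximum-HU
threshold; the high-density-without-severe-artifact subcategory requires
explicit per-slice flags from the caller (in a clinic that judgement is
visual; the synthetic generator records it in its manifest).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from . import losses
from .io_prep import METAL_THRESHOLD_HU, CTVolume, NormalizationWindow, normalize

CATEGORY_ALL = "all"
CATEGORY_METAL_FREE = "metal_free"
CATEGORY_METAL = "metal_containing"
CATEGORY_HIGH_DENSITY_OK = "high_density_no_severe_artifact"

DEFAULT_EVAL_WINDOW = NormalizationWindow(hu_min=-1000.0, hu_max=1500.0)


def mae_hu(a: np.ndarray, b: np.ndarray,
           mask: np.ndarray | None = None) -> float:
    """Mean absolute error in HU over an optional mask (default: all pixels)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    diff = np.abs(a - b)
    if mask is None:
        return float(diff.mean())
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(diff[mask].mean())


def ssim_hu(a: np.ndarray, b: np.ndarray,
            window: NormalizationWindow = DEFAULT_EVAL_WINDOW,
            weights: losses.LossWeights | None = None) -> float:
    """SSIM of two HU slices after windowing to the display range."""
    return losses.ssim(normalize(a, window), normalize(b, window), weights)


@dataclass
class ReportRow:
    comparison: str
    category: str
    n_slices: int
    ssim: float
    mae_hu: float


@dataclass
class EvalReport:
    rows: list[ReportRow] = field(default_factory=list)

    def row(self, comparison: str, category: str = CATEGORY_ALL) -> ReportRow:
        for r in self.rows:
            if r.comparison == comparison and r.category == category:
                return r
        raise KeyError(f"no row ({comparison!r}, {category!r})")

    def to_dict(self) -> dict:
        return {"rows": [vars(r) for r in self.rows]}

    def write_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["comparison", "category", "n_slices", "ssim",
                             "mae_hu"])
            for r in self.rows:
                writer.writerow([r.comparison, r.category, r.n_slices,
                                 r.ssim, r.mae_hu])


def build_report(comparisons: dict[str, list[tuple[CTVolume, CTVolume]]],
                 threshold_hu: float = METAL_THRESHOLD_HU,
                 no_severe_flags: dict[str, list[bool]] | None = None,
                 window: NormalizationWindow = DEFAULT_EVAL_WINDOW,
                 ) -> EvalReport:
    """Aggregate per-slice SSIM/MAE for named (predicted, truth) volume pairs.

    ``comparisons`` maps a row name to a list of aligned volume pairs (one
    per study). Categories are assigned per slice from the truth volume's
    max HU; ``no_severe_flags`` (keyed like comparisons' study lists,
    flattened slice-wise per comparison) marks high-density slices without
    severe artifacts for the extra subcategory row.
    """
    report = EvalReport()
    for name, volume_pairs in comparisons.items():
        if not volume_pairs:
            raise ValueError(f"comparison {name!r} has no volumes")
        per_slice: list[tuple[str, bool, float, float]] = []
        flags = no_severe_flags.get(name) if no_severe_flags else None
        idx = 0
        for pred, truth in volume_pairs:
            if pred.voxels.shape != truth.voxels.shape:
                raise ValueError(f"misaligned volumes in {name!r}")
            for k in range(truth.n_slices):
                t = truth.slice_at(k)
                p = pred.slice_at(k)
                high = float(t.max()) > threshold_hu
                category = CATEGORY_METAL if high else CATEGORY_METAL_FREE
                no_severe = bool(flags[idx]) if flags is not None else False
                per_slice.append((category, high and no_severe,
                                  ssim_hu(p, t, window), mae_hu(p, t)))
                idx += 1

        def _aggregate(category: str, rows):
            if rows:
                report.rows.append(ReportRow(
                    comparison=name, category=category, n_slices=len(rows),
                    ssim=float(np.mean([r[2] for r in rows])),
                    mae_hu=float(np.mean([r[3] for r in rows]))))

        _aggregate(CATEGORY_ALL, per_slice)
        _aggregate(CATEGORY_METAL_FREE,
                   [r for r in per_slice if r[0] == CATEGORY_METAL_FREE])
        _aggregate(CATEGORY_METAL,
                   [r for r in per_slice if r[0] == CATEGORY_METAL])
        _aggregate(CATEGORY_HIGH_DENSITY_OK,
                   [r for r in per_slice if r[1]])
    return report
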