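"""Region-level matching of predicted vs manual lesions and case-level calls.

Connected components (26-connectivity) are computed for the predicted and the
manual masks.  A manual component with at least one overlapping predicted
voxel counts as exactly one true positive, even if several predicted
components touch it; predicted components overlapping no manual component are
false positives; manual components with no overlap are false negatives.
Predicted labels outside the lung parenchyma are ignored.

A whole case is called positive when the mean network probability over the
lung is at or above a cutoff (0.55 by default, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volio import BinaryMask, CTVolume, ProbabilityMap

__all__ = [
    "RegionMatchResult",
    "CaseHuSummary",
    "match_regions",
    "classify_case",
    "case_hu_summary",
    "DEFAULT_CASE_CUTOFF",
]

DEFAULT_CASE_CUTOFF = 0.55

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class RegionMatchResult:
    n_true_positive_regions: int
    n_false_positive_regions: int
    n_false_negative_regions: int
    #: volume (mL) of every manual region, matched or not
    manual_region_volumes_ml: list[float] = field(default_factory=list)
    #: volume (mL) of every false-positive predicted region
    false_positive_volumes_ml: list[float] = field(default_factory=list)

    @property
    def n_manual_regions(self) -> int:
        return self.n_true_positive_regions + self.n_false_negative_regions


def match_regions(
    pred_mask: BinaryMask, truth_mask: BinaryMask, lung: BinaryMask
) -> RegionMatchResult:
    """Match predicted components to manual components by >=1 voxel overlap."""
    if not (pred_mask.shape == truth_mask.shape == lung.shape):
        raise ValueError(
            f"grid mismatch: pred {pred_mask.shape}, truth {truth_mask.shape}, "
            f"lung {lung.shape}"
        )
    voxel_ml = float(np.prod(lung.spacing)) / 1000.0
    pred = pred_mask.data & lung.data  # ignore predictions outside the lung
    truth = truth_mask.data

    truth_lab, n_truth = ndimage.label(truth, structure=_STRUCT26)
    pred_lab, n_pred = ndimage.label(pred, structure=_STRUCT26)

    overlap = pred & truth
    matched_truth = np.unique(truth_lab[overlap]) if overlap.any() else np.array([], int)
    matched_pred = np.unique(pred_lab[overlap]) if overlap.any() else np.array([], int)

    n_tp = int(len(matched_truth))
    n_fn = int(n_truth - n_tp)
    fp_ids = np.setdiff1d(np.arange(1, n_pred + 1), matched_pred)
    n_fp = int(len(fp_ids))

    truth_counts = np.bincount(truth_lab.ravel(), minlength=n_truth + 1)
    manual_vols = [float(truth_counts[i] * voxel_ml) for i in range(1, n_truth + 1)]
    pred_counts = np.bincount(pred_lab.ravel(), minlength=n_pred + 1)
    fp_vols = [float(pred_counts[i] * voxel_ml) for i in fp_ids]

    return RegionMatchResult(
        n_true_positive_regions=n_tp,
        n_false_positive_regions=n_fp,
        n_false_negative_regions=n_fn,
        manual_region_volumes_ml=manual_vols,
        false_positive_volumes_ml=fp_vols,
    )


def classify_case(
    prob_map: ProbabilityMap, lung: BinaryMask, cutoff: float = DEFAULT_CASE_CUTOFF
) -> tuple[bool, float]:
    """Case-level call: mean lung probability at or above ``cutoff`` is positive."""
    if prob_map.shape != lung.shape:
        raise ValueError(f"grid mismatch: map {prob_map.shape} vs lung {lung.shape}")
    if not lung.data.any():
        raise ValueError("lung mask is empty")
    mean_prob = float(prob_map.data[lung.data].mean())
    return mean_prob >= cutoff, mean_prob


@dataclass(frozen=True)
class CaseHuSummary:
    """Two candidate HU readings for a case, plus the overall lung mean.

    ``fraction_below`` is the fraction of lung voxels at or below the
    threshold; ``mean_hu_below`` is the mean HU over those voxels (``None``
    when there are none).  Both readings of the ambiguous "mean over the lung
    tissue with < -850 HU" phrase are reported and labelled; neither is
    asserted as canonical.
    """

    fraction_below: float
    mean_hu_below: float | None
    mean_lung_hu: float
    threshold_hu: float


def case_hu_summary(
    vol: CTVolume, lung: BinaryMask, threshold_hu: float = -850.0
) -> CaseHuSummary:
    if vol.shape != lung.shape:
        raise ValueError(f"grid mismatch: volume {vol.shape} vs lung {lung.shape}")
    if not lung.data.any():
        raise ValueError("lung mask is empty")
    hu = np.asarray(vol.data, dtype=np.float64)[lung.data]
    below = hu <= threshold_hu
    frac = float(below.mean())
    mean_below = float(hu[below].mean()) if below.any() else None
    return CaseHuSummary(
        fraction_below=frac,
        mean_hu_below=mean_below,
        mean_lung_hu=float(hu.mean()),
        threshold_hu=float(threshold_hu),
    )
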