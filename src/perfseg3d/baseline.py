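"""Naive Hounsfield-unit-threshold comparator.

The comparison method labels every lung voxel whose attenuation is at or
below a global threshold (default -850 HU, inclusive) as hypoattenuating.
No clustering or smoothing is applied.  For ROC analysis the continuous
score is the negated HU value, so that higher scores mean more
hypoattenuating and the same machinery used for the network's probability
maps applies.
"""

from __future__ import annotations

import numpy as np

from .volio import BinaryMask, CTVolume

__all__ = ["hu_threshold_segment", "hu_score_map", "DEFAULT_THRESHOLD_HU"]

DEFAULT_THRESHOLD_HU = -850.0


def _check_grid(vol: CTVolume, lung: BinaryMask) -> None:
    if vol.shape != lung.shape:
        raise ValueError(f"grid mismatch: volume {vol.shape} vs lung {lung.shape}")
    if not np.allclose(vol.spacing, lung.spacing):
        raise ValueError(
            f"spacing mismatch: volume {vol.spacing} vs lung {lung.spacing}"
        )


def hu_threshold_segment(
    vol: CTVolume, lung: BinaryMask, threshold_hu: float = DEFAULT_THRESHOLD_HU
) -> BinaryMask:
    """Label lung voxels with HU <= ``threshold_hu`` (inclusive) as positive."""
    _check_grid(vol, lung)
    mask = lung.data & (vol.data <= threshold_hu)
    return BinaryMask(mask, vol.spacing, vol.affine)


def hu_score_map(vol: CTVolume, lung: BinaryMask) -> np.ndarray:
    """Continuous hypoattenuation score: negated HU on lung voxels.

    Returns a float array of shape ``vol.shape`` equal to ``-HU`` inside the
    lung and ``-inf`` outside it; voxels outside the lung carry no score and
    are excluded from every evaluation.  Thresholding the score at ``+850``
    reproduces :func:`hu_threshold_segment` at ``-850``.
    """
    _check_grid(vol, lung)
    score = np.where(lung.data, -np.asarray(vol.data, dtype=np.float64), -np.inf)
    return score
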