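"""Resampling to an isotropic grid and HU intensity normalization.

CT angiography volumes are resampled to a uniform isotropic voxel size
(1 x 1 x 1 mm by default) and intensities are normalized by linearly mapping
the -900...-600 HU range onto -1...1:

    y = (x + 750) / 150

No clipping is applied: values outside [-900, -600] map linearly outside
[-1, 1], preserving vessel and soft-tissue contrast.  The map is exactly
invertible (:func:`denormalize_hu`).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volio import BinaryMask, CTVolume

__all__ = [
    "resample_isotropic",
    "normalize_hu",
    "denormalize_hu",
    "naive_lung_mask",
    "HU_WINDOW",
]

#: the HU range mapped onto [-1, 1]
HU_WINDOW = (-900.0, -600.0)

_CENTER = -(HU_WINDOW[0] + HU_WINDOW[1]) / 2.0  # +750
_HALFWIDTH = (HU_WINDOW[1] - HU_WINDOW[0]) / 2.0  # 150


def _target_shape(shape, spacing, target: float) -> tuple[int, ...]:
    # round-half-away-from-zero of (extent / target), at least 1 voxel
    out = []
    for n, s in zip(shape, spacing):
        x = n * s / target
        out.append(max(1, int(np.floor(x + 0.5))))
    return tuple(out)


def resample_isotropic(vol, target_mm: float = 1.0):
    """Resample a :class:`CTVolume` or :class:`BinaryMask` to isotropic spacing.

    Images are interpolated trilinearly, masks with nearest neighbour (so
    they remain strictly binary).  The output shape on each axis is
    ``round(shape * spacing / target_mm)`` with ties rounded away from zero.
    If the input is already at the target spacing the data is returned
    unchanged (identity short-circuit).
    """
    if target_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_mm}")
    is_mask = isinstance(vol, BinaryMask)
    spacing = vol.spacing
    if all(abs(s - target_mm) < 1e-9 for s in spacing):
        cls = type(vol)
        return cls(data=vol.data.copy(), spacing=(target_mm,) * 3, affine=vol.affine)

    out_shape = _target_shape(vol.data.shape, spacing, target_mm)
    zoom = [o / n for o, n in zip(out_shape, vol.data.shape)]
    if is_mask:
        data = ndimage.zoom(vol.data.astype(np.uint8), zoom, order=0, mode="nearest")
        data = data.astype(bool)
    else:
        data = ndimage.zoom(
            np.asarray(vol.data, dtype=np.float32), zoom, order=1, mode="nearest"
        )
    if data.shape != out_shape:  # pragma: no cover - zoom rounding safeguard
        raise RuntimeError(f"resampler produced {data.shape}, expected {out_shape}")
    cls = type(vol)
    return cls(data=data, spacing=(target_mm,) * 3, affine=None)


def normalize_hu(vol: CTVolume) -> CTVolume:
    """Map HU intensities linearly so that -900 -> -1 and -600 -> +1."""
    data = (np.asarray(vol.data, dtype=np.float32) + _CENTER) / _HALFWIDTH
    return CTVolume(data=data, spacing=vol.spacing, affine=vol.affine)


def denormalize_hu(vol: CTVolume) -> CTVolume:
    """Exact inverse of :func:`normalize_hu`."""
    data = np.asarray(vol.data, dtype=np.float32) * _HALFWIDTH - _CENTER
    return CTVolume(data=data, spacing=vol.spacing, affine=vol.affine)


def naive_lung_mask(vol: CTVolume, threshold_hu: float = -300.0) -> BinaryMask:
    """Convenience lung segmentation for demos.

    Thresholds air-like voxels (HU < ``threshold_hu``), discards connected
    components touching the volume border (ambient air), keeps the two
    largest remaining components (the lungs) and applies a morphological
    closing to fill vessels.  All pipeline stages accept an externally
    supplied lung mask; this helper only exists so the tool can run without
    one.  If nothing lung-like is found an empty mask is returned.
    """
    air = vol.data < threshold_hu
    labels, n = ndimage.label(air)
    if n == 0:
        return BinaryMask(np.zeros(vol.shape, bool), vol.spacing, vol.affine)
    border = np.zeros(vol.shape, bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    touching = np.unique(labels[border])
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    counts[0] = 0
    counts[touching] = 0
    keep = np.argsort(counts)[::-1][:2]
    keep = [k for k in keep if counts[k] > 0]
    if not keep:
        return BinaryMask(np.zeros(vol.shape, bool), vol.spacing, vol.affine)
    mask = np.isin(labels, keep)
    mask = ndimage.binary_closing(mask, structure=ndimage.generate_binary_structure(3, 2), iterations=2)
    return BinaryMask(mask, vol.spacing, vol.affine)
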