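"""Volumetric data model and NIfTI-1 input/output.

Every stage of the pipeline works on three kinds of 3-D fields defined on a
common voxel grid:

* :class:`CTVolume` -- scalar attenuation in Hounsfield units (HU),
* :class:`BinaryMask` -- a boolean field (lung segmentation or lesion label),
* :class:`ProbabilityMap` -- per-voxel values in [0, 1] (network output).

Conventions
-----------
Voxel indexing is 0-based and all shapes/coordinates are expressed in index
space.  Axis order follows the array as nibabel presents it (``data[i, j, k]``
with axis 0 the first on-disk image axis); the pipeline never permutes axes.
``spacing`` is the per-axis voxel size in millimetres.  World-space
information (the 4x4 affine) is carried through unchanged when present but
never interpreted.

The physical volume of a mask in millilitres is
``count(True) * spacing[0] * spacing[1] * spacing[2] / 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "BinaryMask",
    "ProbabilityMap",
    "read_volume",
    "read_mask",
    "read_probability_map",
    "write_volume",
    "mask_volume_ml",
]


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A 3-D scalar field in Hounsfield units with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class BinaryMask:
    """A 3-D boolean field on the same grid as its parent volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask values must be strictly {0, 1}")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def volume_ml(self) -> float:
        """Physical volume of the mask in millilitres."""
        return self.count() * float(np.prod(self.spacing)) / 1000.0


@dataclass
class ProbabilityMap:
    """A 3-D field of per-voxel probabilities in [0, 1]."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        # float64 so that near-saturated sigmoid outputs keep distinct ranks
        data = np.asarray(self.data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        lo, hi = float(self.data.min(initial=0.0)), float(self.data.max(initial=0.0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"probabilities outside [0, 1]: range [{lo}, {hi}]")
        np.clip(self.data, 0.0, 1.0, out=self.data)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


Volume = Union[CTVolume, BinaryMask, ProbabilityMap]


def mask_volume_ml(mask: BinaryMask) -> float:
    return mask.volume_ml()


def _load(path) -> tuple[np.ndarray, tuple, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3-D NIfTI image, got shape {img.shape}")
    # get_fdata applies the on-disk scl_slope / scl_inter rescaling.
    data = np.asarray(img.get_fdata(dtype=np.float64))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def read_volume(path) -> CTVolume:
    """Read a NIfTI-1 file as a HU-valued :class:`CTVolume`."""
    data, spacing, affine = _load(path)
    return CTVolume(data=data, spacing=spacing, affine=affine)


def read_mask(path) -> BinaryMask:
    """Read a NIfTI-1 file as a :class:`BinaryMask` (values must be {0, 1})."""
    data, spacing, affine = _load(path)
    return BinaryMask(data=data, spacing=spacing, affine=affine)


def read_probability_map(path) -> ProbabilityMap:
    data, spacing, affine = _load(path)
    return ProbabilityMap(data=data, spacing=spacing, affine=affine)


def write_volume(vol: Volume, path) -> None:
    """Write a volume, mask or probability map as NIfTI-1.

    Masks are stored as unsigned 8-bit, everything else as float32.  The
    affine is passed through if present, otherwise a diagonal affine built
    from the spacing is written so the header zooms round-trip exactly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = np.asarray(vol.data, dtype=np.float32)
    if vol.affine is not None:
        affine = np.asarray(vol.affine, dtype=np.float64)
    else:
        affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
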