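"""Patch extraction for training and exact tiled inference.

The network uses valid padding, so an input window of side
``patch + 2 * margin`` produces a label patch of side ``patch``.  Training
samples are drawn uniformly over the volume and a candidate is rejected (and
redrawn) only when its label-patch region contains no lung voxel -- patches
*partially* inside the lung are kept.

For inference, non-overlapping label patches tile the lung bounding box
(clipped to the volume at the edges); each input window is the label patch
grown by the margin, with edge replication where the window leaves the
volume.  Because the network is valid-padded and translation-equivariant,
stitching the per-tile outputs reproduces dense whole-volume inference on the
replication-padded volume exactly -- that identity is the correctness oracle
for all margin handling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .volio import BinaryMask, CTVolume, ProbabilityMap

__all__ = [
    "PatchPlan",
    "sample_training_patches",
    "plan_inference_tiles",
    "extract_window",
    "stitch",
]

DEFAULT_PATCH = 32
DEFAULT_MARGIN = 30


@dataclass(frozen=True)
class PatchPlan:
    """Non-overlapping label-patch tiling of (part of) a volume.

    ``placements`` holds the start index of each label patch; edge tiles are
    clipped to the volume, so a tile's effective size on axis ``a`` is
    ``min(label_patch_size, volume_shape[a] - start[a])``.  Input windows are
    always ``(label_patch_size + 2 * margin)`` per side, taken with edge
    replication beyond the volume.
    """

    label_patch_size: int
    margin: int
    placements: tuple[tuple[int, int, int], ...]
    volume_shape: tuple[int, int, int]
    padding_mode: str = "edge-replicate"

    @property
    def window_size(self) -> int:
        return self.label_patch_size + 2 * self.margin

    def tile_extent(self, start) -> tuple[tuple[int, int], ...]:
        """Clipped [start, stop) extent of the label patch on each axis."""
        return tuple(
            (s, min(s + self.label_patch_size, n))
            for s, n in zip(start, self.volume_shape)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "label_patch_size": self.label_patch_size,
                "margin": self.margin,
                "volume_shape": list(self.volume_shape),
                "padding_mode": self.padding_mode,
                "placements": [list(p) for p in self.placements],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "PatchPlan":
        d = json.loads(s)
        return cls(
            label_patch_size=d["label_patch_size"],
            margin=d["margin"],
            placements=tuple(tuple(p) for p in d["placements"]),
            volume_shape=tuple(d["volume_shape"]),
            padding_mode=d["padding_mode"],
        )


def extract_window(data: np.ndarray, start, size: int, margin: int) -> np.ndarray:
    """Input window for the label patch at ``start``: the full nominal patch
    footprint grown by ``margin``, padded by edge replication where it leaves
    the volume."""
    lo = [s - margin for s in start]
    hi = [s + size + margin for s in start]
    pad = []
    sl = []
    for a in range(3):
        lo_clip = max(lo[a], 0)
        hi_clip = min(hi[a], data.shape[a])
        pad.append((lo_clip - lo[a], hi[a] - hi_clip))
        sl.append(slice(lo_clip, hi_clip))
    window = data[tuple(sl)]
    if any(p != (0, 0) for p in pad):
        window = np.pad(window, pad, mode="edge")
    return window


def sample_training_patches(
    vol: CTVolume,
    lung: BinaryMask,
    label: BinaryMask,
    patch: int = DEFAULT_PATCH,
    margin: int = DEFAULT_MARGIN,
    n: int = 32,
    seed: int = 0,
    lesion_oversample: float = 0.0,
    max_attempts_factor: int = 1000,
):
    """Draw ``n`` training samples of (input window, label patch, lung patch).

    Candidate label-patch placements are uniform over the volume; placements
    whose label-patch region contains zero lung voxels are rejected and
    redrawn.  ``lesion_oversample`` is the fraction of samples additionally
    required to contain at least one lesion voxel (0 = plain uniform
    sampling over accepted candidates); it is drawn by rejection, so a case
    without lesions falls back to uniform sampling.  Deterministic for a
    fixed seed.
    """
    if not (vol.shape == lung.shape == label.shape):
        raise ValueError("volume, lung and label must share one grid")
    if not lung.data.any():
        raise ValueError("lung mask is empty: no valid patch exists")
    if any(dim < patch for dim in vol.shape):
        raise ValueError(f"volume {vol.shape} smaller than patch size {patch}")
    rng = np.random.default_rng(seed)
    data = np.asarray(vol.data, dtype=np.float32)
    has_lesions = bool(label.data.any())
    n_lesion = int(round(lesion_oversample * n)) if has_lesions else 0
    out = []
    attempts = 0
    max_attempts = max_attempts_factor * n
    while len(out) < n:
        if attempts >= max_attempts:
            raise RuntimeError("patch rejection rate too high; is the lung tiny?")
        attempts += 1
        start = tuple(
            int(rng.integers(0, dim - patch + 1)) for dim in vol.shape
        )
        region = tuple(slice(s, s + patch) for s in start)
        lung_patch = lung.data[region]
        if not lung_patch.any():
            continue  # completely outside the lung region -> rejected
        label_patch = label.data[region]
        if len(out) < n_lesion and not label_patch.any():
            continue  # this slot requires lesion content
        window = extract_window(data, start, patch, margin)
        out.append((window, label_patch.copy(), lung_patch.copy()))
    return out


def plan_inference_tiles(
    volume_shape, lung: BinaryMask, patch: int, margin: int
) -> PatchPlan:
    """Non-overlapping label-patch grid covering the lung bounding box.

    The grid starts at the bounding-box corner with stride ``patch``; edge
    tiles are clipped to the volume; tiles containing no lung voxel are
    omitted.
    """
    if patch < 1:
        raise ValueError("patch must be >= 1")
    volume_shape = tuple(int(v) for v in volume_shape)
    if lung.shape != volume_shape:
        raise ValueError(f"lung {lung.shape} does not match volume {volume_shape}")
    if not lung.data.any():
        return PatchPlan(patch, margin, (), volume_shape)
    nz = np.argwhere(lung.data)
    bb_lo = nz.min(axis=0)
    bb_hi = nz.max(axis=0) + 1
    axes = []
    for a in range(3):
        # snap the grid to multiples of the patch size so every tile shares
        # one pooling alignment (and tiling matches a dense pass exactly)
        first = (int(bb_lo[a]) // patch) * patch
        starts = list(range(first, int(bb_hi[a]), patch))
        axes.append(starts)
    placements = []
    for s0 in axes[0]:
        for s1 in axes[1]:
            for s2 in axes[2]:
                start = (s0, s1, s2)
                region = tuple(
                    slice(s, min(s + patch, n)) for s, n in zip(start, volume_shape)
                )
                if lung.data[region].any():
                    placements.append(start)
    return PatchPlan(patch, margin, tuple(placements), volume_shape)


def stitch(plan: PatchPlan, patch_outputs, spacing=None) -> ProbabilityMap:
    """Place per-tile outputs into a full-volume probability map.

    Each output must be the nominal ``patch``-cube (edge tiles are cropped to
    their clipped extent here) or already clipped.  Voxels covered by no tile
    are 0; no voxel is written twice.
    """
    if len(patch_outputs) != len(plan.placements):
        raise ValueError(
            f"{len(patch_outputs)} outputs for {len(plan.placements)} placements"
        )
    dtype = np.asarray(patch_outputs[0]).dtype if len(patch_outputs) else np.float32
    out = np.zeros(plan.volume_shape, dtype=dtype)
    p = plan.label_patch_size
    for start, tile in zip(plan.placements, patch_outputs):
        tile = np.asarray(tile)
        extent = plan.tile_extent(start)
        sizes = tuple(hi - lo for lo, hi in extent)
        if tile.shape == (p, p, p):
            tile = tile[tuple(slice(0, s) for s in sizes)]
        elif tile.shape != sizes:
            raise ValueError(
                f"tile at {start} has shape {tile.shape}, expected {sizes} or "
                f"{(p, p, p)}"
            )
        out[tuple(slice(lo, hi) for lo, hi in extent)] = tile
    return ProbabilityMap(out, spacing if spacing is not None else (1.0, 1.0, 1.0))
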