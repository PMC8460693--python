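"""Synthetic CTPA-like phantom cohorts with ground-truth hypoperfusion labels.

Every downstream stage (preprocessing, patch sampling, network training,
HU-threshold baseline, evaluation) is exercised on these phantoms, so the
generator reproduces the *structure* of the clinical problem rather than CT
physics:

* two ellipsoidal lung fields of aerated parenchyma (default -780 HU) inside
  a soft-tissue body (+40 HU) surrounded by air (-1000 HU);
* bright tubular vessels radiating from a hilum point in each lung;
* in positive cases, well-demarcated hypoattenuating lesions (default
  -900 HU) built as unions of smoothed random ellipsoids (metaball-style)
  with sigmoid-graded borders, sized so that lesions occupy a configurable
  fraction of the lung (default 21%) and every connected component is at
  least 5 mL -- smaller components are removed from both image and label;
* beam-hardening-like streaks: oriented low-HU Gaussian-profile bands
  anchored on the lung border, added AFTER the label is frozen so they are
  unlabelled confounders (the main false-positive source for a pure HU
  threshold);
* Gaussian HU noise, also added after label creation.

The default lesion/parenchyma contrast (120 HU) is deliberately below four
noise standard deviations (4 x 40 HU), so single-voxel thresholding is
imperfect and the network-vs-baseline comparison is non-degenerate.  A fixed
seed reproduces a case voxel for voxel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volio import BinaryMask, CTVolume

__all__ = ["PhantomConfig", "PhantomCase", "generate_case", "generate_cohort"]

AIR_HU = -1000.0
SOFT_TISSUE_HU = 40.0
VESSEL_HU = 150.0
HU_MIN, HU_MAX = -1024.0, 3071.0


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration cannot be realised."""


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic case."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    normal_parenchyma_hu: float = -780.0
    hypoperfused_hu: float = -900.0
    hu_noise_sd: float = 40.0
    lesion_fraction_target: float = 0.21
    min_lesion_ml: float = 5.0
    n_lesions_range: tuple[int, int] = (2, 4)
    vessel_density: float = 1.0  # scales the number of vessel branches
    artifact_streaks: int = 4
    border_softness_mm: float = 3.0
    min_lung_ml: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.hypoperfused_hu >= self.normal_parenchyma_hu:
            raise PhantomConfigError(
                "hypoperfused_hu must be below normal_parenchyma_hu"
            )
        if not (0.0 < self.lesion_fraction_target < 1.0):
            raise PhantomConfigError("lesion_fraction_target must be in (0, 1)")
        if self.min_lesion_ml <= 0:
            raise PhantomConfigError("min_lesion_ml must be positive")
        if self.n_lesions_range[0] < 1 or self.n_lesions_range[0] > self.n_lesions_range[1]:
            raise PhantomConfigError("invalid n_lesions_range")
        if min(self.shape) < 32:
            raise PhantomConfigError("shape must be at least 32 voxels per axis")

    @property
    def voxel_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass
class PhantomCase:
    """One synthetic study case (positive or negative analogue)."""

    volume: CTVolume
    lung_mask: BinaryMask
    lesion_mask: BinaryMask
    is_positive: bool
    seed: int
    case_id: str = ""


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _lung_fields(cfg: PhantomConfig, rng) -> np.ndarray:
    shape = np.asarray(cfg.shape, float)
    lungs = np.zeros(cfg.shape, dtype=bool)
    for side in (0.30, 0.70):
        jitter = rng.uniform(0.95, 1.05, size=3)
        semi = np.array([0.32, 0.17, 0.25]) * shape * jitter
        center = np.array([0.5, side, 0.5]) * shape + rng.uniform(-1.5, 1.5, size=3)
        lungs |= _ellipsoid(cfg.shape, center, semi)
    return lungs


def _draw_vessels(cfg: PhantomConfig, rng, lungs: np.ndarray) -> np.ndarray:
    """Tubular bright structures: line segments from a hilum point, dilated."""
    vessels = np.zeros(cfg.shape, dtype=bool)
    shape = np.asarray(cfg.shape, float)
    n_branches = max(1, int(round(8 * cfg.vessel_density)))
    idx = np.argwhere(lungs)
    if idx.size == 0:
        return vessels
    for side in (0.35, 0.65):
        hilum = np.array([0.5, side, 0.42]) * shape
        for _ in range(n_branches):
            target = idx[rng.integers(0, len(idx))]
            length = np.linalg.norm(target - hilum)
            n_steps = max(2, int(length * 2))
            ts = np.linspace(0.0, 1.0, n_steps)[:, None]
            pts = hilum[None, :] * (1 - ts) + target[None, :] * ts
            pts = np.round(pts).astype(int)
            np.clip(pts, 0, np.asarray(cfg.shape) - 1, out=pts)
            vessels[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    vessels = ndimage.binary_dilation(vessels, iterations=1)
    return vessels & lungs


def _lesion_field(cfg: PhantomConfig, rng, lungs: np.ndarray) -> np.ndarray:
    """Soft lesion occupancy in [0, 1]; label is its 0.5 superlevel set."""
    lung_vox = int(lungs.sum())
    min_vox = cfg.min_lesion_ml / cfg.voxel_ml
    target_vox = cfg.lesion_fraction_target * lung_vox
    n_lo, n_hi = cfg.n_lesions_range
    n_lesions = int(rng.integers(n_lo, n_hi + 1))
    # shrink the lesion count until each part is comfortably above the 5 mL
    # floor; if even a single lesion cannot reach it the target is infeasible
    while n_lesions > 1 and target_vox / n_lesions < 2.0 * min_vox:
        n_lesions -= 1
    if target_vox < min_vox:
        raise PhantomConfigError(
            f"lesion_fraction_target {cfg.lesion_fraction_target} yields "
            f"{target_vox * cfg.voxel_ml:.1f} mL of lesion, below the "
            f"{cfg.min_lesion_ml} mL minimum"
        )

    parts = rng.dirichlet(np.full(n_lesions, 8.0)) * target_vox
    support = np.zeros(cfg.shape, dtype=bool)
    mean_r = (3.0 * target_vox / n_lesions / (4.0 * np.pi)) ** (1.0 / 3.0)
    interior = ndimage.binary_erosion(lungs, iterations=max(1, int(mean_r * 0.6)))
    centers_pool = np.argwhere(interior if interior.any() else lungs)
    for part in parts:
        center = centers_pool[rng.integers(0, len(centers_pool))].astype(float)
        # 2-3 overlapping ellipsoids around the centre for an irregular blob
        n_sub = int(rng.integers(2, 4))
        r0 = (3.0 * part / n_sub / (4.0 * np.pi)) ** (1.0 / 3.0) * 1.15
        for _ in range(n_sub):
            offs = rng.normal(0.0, r0 * 0.45, size=3)
            semi = r0 * rng.uniform(0.75, 1.35, size=3)
            semi = np.maximum(semi, 2.5)
            support |= _ellipsoid(cfg.shape, center + offs, semi)
    support &= lungs

    # enforce the minimum component volume BEFORE grading the border, so the
    # label is exactly the support and both stay consistent with the image
    lab, n = ndimage.label(support, structure=np.ones((3, 3, 3), bool))
    if n:
        counts = np.bincount(lab.ravel(), minlength=n + 1)
        small = np.flatnonzero(counts[1:] * cfg.voxel_ml < cfg.min_lesion_ml) + 1
        if small.size:
            support &= ~np.isin(lab, small)

    # well-demarcated lesions: full-depth plateau with a sigmoid-graded
    # border of width border_softness_mm, built from the signed Euclidean
    # distance to the lesion surface (in mm)
    if support.any():
        spacing = np.asarray(cfg.spacing_mm, dtype=float)
        d_in = ndimage.distance_transform_edt(support, sampling=spacing)
        d_out = ndimage.distance_transform_edt(~support, sampling=spacing)
        signed = d_in - d_out
        soft = 1.0 / (1.0 + np.exp(-4.0 * signed / cfg.border_softness_mm))
        soft = np.where(lungs, soft, 0.0).astype(np.float32)
    else:
        soft = np.zeros(cfg.shape, dtype=np.float32)
    label = support & lungs
    return soft, label


def _streaks(cfg: PhantomConfig, rng, lungs: np.ndarray) -> np.ndarray:
    """Beam-hardening-like bands: planar low-HU Gaussian profiles anchored on
    the lung border with a finite lateral extent."""
    offset = np.zeros(cfg.shape, dtype=np.float32)
    if cfg.artifact_streaks <= 0:
        return offset
    border = lungs & ~ndimage.binary_erosion(lungs)
    anchors = np.argwhere(border)
    if anchors.size == 0:
        return offset
    grids = np.ogrid[tuple(slice(0, n) for n in cfg.shape)]
    for _ in range(cfg.artifact_streaks):
        p0 = anchors[rng.integers(0, len(anchors))].astype(float)
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        depth = rng.uniform(80.0, 150.0)
        width = rng.uniform(1.5, 3.0)
        reach = rng.uniform(8.0, 16.0)
        d_plane = np.zeros(cfg.shape, dtype=np.float32)
        d2_point = np.zeros(cfg.shape, dtype=np.float32)
        for g, c, nv in zip(grids, p0, normal):
            d_plane = d_plane + (g - c) * nv
            d2_point = d2_point + (g - c) ** 2
        offset -= depth * np.exp(
            -(d_plane**2) / (2.0 * width**2) - d2_point / (2.0 * reach**2)
        )
    return offset


def generate_case(cfg: PhantomConfig, positive: bool) -> PhantomCase:
    """Generate one phantom case; deterministic for a fixed ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    shape = np.asarray(cfg.shape, float)

    body = _ellipsoid(cfg.shape, shape * 0.5, shape * np.array([0.47, 0.45, 0.48]))
    lungs = _lung_fields(cfg, rng) & body
    lung_ml = lungs.sum() * cfg.voxel_ml
    if lung_ml < cfg.min_lung_ml:
        raise PhantomConfigError(
            f"phantom lungs hold only {lung_ml:.0f} mL "
            f"(< {cfg.min_lung_ml} mL); enlarge shape or spacing"
        )

    img = np.full(cfg.shape, AIR_HU, dtype=np.float32)
    img[body] = SOFT_TISSUE_HU
    img[lungs] = cfg.normal_parenchyma_hu
    vessels = _draw_vessels(cfg, rng, lungs)
    img[vessels] = VESSEL_HU

    if positive:
        soft, label = _lesion_field(cfg, rng, lungs)
        img = img + (cfg.hypoperfused_hu - cfg.normal_parenchyma_hu) * soft
    else:
        label = np.zeros(cfg.shape, dtype=bool)

    # label is frozen here; streaks and noise are unlabelled confounders
    img = img + _streaks(cfg, rng, lungs)
    if cfg.hu_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.hu_noise_sd, cfg.shape).astype(np.float32)
    np.clip(img, HU_MIN, HU_MAX, out=img)

    spacing = tuple(cfg.spacing_mm)
    return PhantomCase(
        volume=CTVolume(img, spacing),
        lung_mask=BinaryMask(lungs, spacing),
        lesion_mask=BinaryMask(label, spacing),
        is_positive=bool(positive),
        seed=int(cfg.seed),
    )


def generate_cohort(
    cfg: PhantomConfig, n_positive: int, n_negative: int, seed: int
) -> list[PhantomCase]:
    """Cohort of independent cases: positives first, then negatives.

    Per-case seeds are derived from the master seed with
    ``numpy.random.SeedSequence`` so the cohort is reproducible and cases are
    mutually independent.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("case counts must be non-negative")
    n = n_positive + n_negative
    if n == 0:
        return []
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    cases = []
    for i in range(n):
        positive = i < n_positive
        case_cfg = dataclasses.replace(cfg, seed=int(child_seeds[i]))
        case = generate_case(case_cfg, positive)
        case.case_id = f"case{i:03d}"
        cases.append(case)
    return cases
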