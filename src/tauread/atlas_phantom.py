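"""Synthetic atlases, single-scan phantoms, and study-like cohorts.

The phantom abstraction is deliberately simple: each cortical region-side is
painted at a designed multiple of the cerebellar mean, then optionally
smoothed (Gaussian, FWHM in mm) and degraded with additive Gaussian noise.
Because the stratification thresholds are multiples of the cerebellar mean,
phantom "multipliers" map directly onto the quantities the visual read
thresholds (1.65x and 2.80x) test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .imaging_io import (
    CEREBELLUM,
    CORTICAL_REGION_SIDES,
    RegionAtlas,
    VoxelGrid3D,
)

# Fractional [start, stop) extents of each region box along (x, y, z), where
# x runs left->right, y posterior->anterior, z inferior->superior. Left-side
# boxes use X_SIDE; right-side boxes are mirror images across the mid-sagittal
# plane. Pairwise disjointness is re-checked at build time.
_X_SIDE = (0.06, 0.44)
_REGION_BOXES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    # name -> ((y0, y1), (z0, z1))
    "lateral_anterior_temporal": ((0.55, 0.80), (0.26, 0.44)),
    "lateral_posterior_temporal": ((0.28, 0.50), (0.26, 0.44)),
    "occipital": ((0.04, 0.20), (0.46, 0.78)),
    "parietal": ((0.40, 0.62), (0.62, 0.90)),
    "precuneus": ((0.20, 0.36), (0.62, 0.90)),
    "frontal": ((0.68, 0.95), (0.50, 0.88)),
}
_CEREBELLUM_BOX = ((0.30, 0.70), (0.04, 0.30), (0.02, 0.22))  # (x, y, z)

MIN_REGION_VOXELS = 50

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Background intensity as a fraction of the cerebellar mean. Chosen so the
#: 1.65x threshold never fires on background, mimicking sub-cerebellar
#: white-matter contrast.
BACKGROUND_FRACTION = 0.5


def _span(frac: tuple[float, float], n: int) -> slice:
    return slice(int(round(frac[0] * n)), int(round(frac[1] * n)))


def _mirror(sl: slice, n: int) -> slice:
    return slice(n - sl.stop, n - sl.start)


def build_synthetic_atlas(
    shape: tuple[int, int, int] = (48, 48, 48),
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> RegionAtlas:
    """Deterministic geometric parcellation hosting the 13 named regions.

    The cerebellum is an inferior block; the 12 cortical region-sides are
    disjoint boxes mirrored across the mid-sagittal plane. Every region gets
    at least :data:`MIN_REGION_VOXELS` voxels or construction fails.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 16 for s in shape):
        raise ValueError(f"shape too small to host 14 disjoint regions: {shape}")
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int16)
    table: dict[int, str] = {}

    def paint(label: int, name: str, xs: slice, ys: slice, zs: slice) -> None:
        block = labels[xs, ys, zs]
        if np.any(block != 0):
            raise ValueError(f"region {name} overlaps an existing region")
        if block.size < MIN_REGION_VOXELS:
            raise ValueError(
                f"shape {shape} too small: region {name} would have {block.size} voxels"
            )
        labels[xs, ys, zs] = label
        table[label] = name

    xs_c, ys_c, zs_c = (_span(f, n) for f, n in zip(_CEREBELLUM_BOX, shape))
    paint(1, CEREBELLUM, xs_c, ys_c, zs_c)

    xs_left = _span(_X_SIDE, nx)
    xs_right = _mirror(xs_left, nx)
    label = 2
    for region, (yf, zf) in _REGION_BOXES.items():
        ys, zs = _span(yf, ny), _span(zf, nz)
        paint(label, f"{region}_L", xs_left, ys, zs)
        paint(label + 1, f"{region}_R", xs_right, ys, zs)
        label += 2

    affine = np.diag(list(voxel_size_mm) + [1.0])
    return RegionAtlas(labels=labels, label_table=table, affine=affine)


@dataclass
class PhantomSpec:
    """Design of a single synthetic scan.

    multipliers
        Regional mean intensity as a multiple of the cerebellar mean, keyed by
        region-side name; missing region-sides default to 1.0.
    noise_sd
        Additive i.i.d. Gaussian noise, in cerebellar-mean units.
    smoothing_fwhm_mm
        Isotropic Gaussian smoothing applied before noise.
    """

    multipliers: Mapping[str, float] = field(default_factory=dict)
    cerebellar_mean: float = 1.0
    noise_sd: float = 0.0
    smoothing_fwhm_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.multipliers) - set(CORTICAL_REGION_SIDES)
        if unknown:
            raise ValueError(f"unknown region name(s) in multipliers: {sorted(unknown)}")
        if self.cerebellar_mean <= 0:
            raise ValueError("cerebellar_mean must be positive")
        if self.noise_sd < 0 or self.smoothing_fwhm_mm < 0:
            raise ValueError("noise_sd and smoothing_fwhm_mm must be nonnegative")
        if any(v < 0 for v in self.multipliers.values()):
            raise ValueError("multipliers must be nonnegative")

    def full_multipliers(self) -> dict[str, float]:
        out = {name: 1.0 for name in CORTICAL_REGION_SIDES}
        out.update({k: float(v) for k, v in self.multipliers.items()})
        return out


def generate_phantom(atlas: RegionAtlas, spec: PhantomSpec) -> VoxelGrid3D:
    """Paint designed regional uptake, then smooth, then add seeded noise."""
    cb = float(spec.cerebellar_mean)
    values = np.full(atlas.shape, BACKGROUND_FRACTION * cb, dtype=np.float64)
    values[atlas.mask(CEREBELLUM)] = cb
    for name, mult in spec.full_multipliers().items():
        values[atlas.mask(name)] = mult * cb
    if spec.smoothing_fwhm_mm > 0:
        voxel_size = np.sqrt((atlas.affine[:3, :3] ** 2).sum(axis=0))
        sigma_vox = spec.smoothing_fwhm_mm * GAUSSIAN_FWHM_TO_SIGMA / voxel_size
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd * cb, size=values.shape)
    return VoxelGrid3D(values=values, affine=atlas.affine.copy())


# Designed multiplier draw ranges for cohort scans. Margins are wide enough
# that smoothing at the default FWHM cannot flip a designed call.
HIGH_TAU_FRONTAL_RANGE = (2.9, 3.6)
NON_HIGH_FRONTAL_RANGE = (1.1, 2.6)
POSTERIOR_AD_RANGE = (1.8, 3.0)
NEGATIVE_RANGE = (0.9, 1.2)
SUBTHRESHOLD_RANGE = (0.9, 1.3)

_POSTERIOR_AD_REGIONS = (
    "lateral_anterior_temporal",
    "lateral_posterior_temporal",
    "occipital",
    "parietal",
    "precuneus",
)
_TAU_PLUS_ELEVATED = ("lateral_anterior_temporal", "lateral_posterior_temporal", "occipital")
_TAU_PLUS_SPARED = ("parietal", "precuneus", "frontal")

TIER_NEGATIVE = "tau_ad_negative"
TIER_PLUS = "tau_ad_plus"
TIER_PLUSPLUS = "tau_ad_plusplus"


@dataclass
class CohortSpec:
    """Composition of a synthetic reader-study cohort.

    Defaults mirror the validation-study scan mix: 70 high-tau and 70
    non-high-tau AD-pattern scans plus 20 tau-negative scans, with ~5% of the
    AD-pattern scans showing only the moderate (tau-AD+) pattern.
    """

    n_high_tau: int = 70
    n_non_high_ad: int = 70
    n_negative: int = 20
    fraction_tau_ad_plus: float = 0.05
    noise_sd: float = 0.0
    smoothing_fwhm_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_high_tau, self.n_non_high_ad, self.n_negative) < 0:
            raise ValueError("cohort counts must be nonnegative")
        if not 0.0 <= self.fraction_tau_ad_plus <= 1.0:
            raise ValueError("fraction_tau_ad_plus must lie in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Designed ground truth carried alongside each cohort scan."""

    scan_id: str
    tier: str
    high_tau: bool


def _draw(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    return float(rng.uniform(*lo_hi))


def _ad_plusplus_multipliers(rng, frontal_range) -> dict[str, float]:
    mult: dict[str, float] = {}
    for region in _POSTERIOR_AD_REGIONS:
        for side in ("L", "R"):
            mult[f"{region}_{side}"] = _draw(rng, POSTERIOR_AD_RANGE)
    for side in ("L", "R"):
        mult[f"frontal_{side}"] = _draw(rng, frontal_range)
    return mult


def _tau_plus_multipliers(rng) -> dict[str, float]:
    mult: dict[str, float] = {}
    for region in _TAU_PLUS_ELEVATED:
        for side in ("L", "R"):
            mult[f"{region}_{side}"] = _draw(rng, POSTERIOR_AD_RANGE)
    for region in _TAU_PLUS_SPARED:
        for side in ("L", "R"):
            mult[f"{region}_{side}"] = _draw(rng, SUBTHRESHOLD_RANGE)
    return mult


def _negative_multipliers(rng) -> dict[str, float]:
    return {name: _draw(rng, NEGATIVE_RANGE) for name in CORTICAL_REGION_SIDES}


def generate_cohort(
    atlas: RegionAtlas, spec: CohortSpec
) -> list[tuple[VoxelGrid3D, TruthRecord]]:
    """Generate a cohort of phantoms with known tier / high-tau ground truth.

    High-tau scans carry the advanced AD pattern with both frontal sides drawn
    above the 2.80x threshold band; non-high AD scans carry the same posterior
    pattern with frontal multipliers below it; negative scans have no region
    near the 1.65x threshold. The moderate-pattern fraction is applied to the
    AD-pattern pool and realised among the non-high scans (a moderate pattern,
    having no frontal involvement, cannot be visually high tau).
    """
    rng = np.random.default_rng(spec.seed)
    n_ad = spec.n_high_tau + spec.n_non_high_ad
    n_plus = min(spec.n_non_high_ad, int(round(spec.fraction_tau_ad_plus * n_ad)))
    plus_positions = set(
        rng.choice(spec.n_non_high_ad, size=n_plus, replace=False).tolist()
    ) if n_plus else set()

    designs: list[tuple[str, bool, dict[str, float]]] = []
    for _ in range(spec.n_high_tau):
        designs.append((TIER_PLUSPLUS, True, _ad_plusplus_multipliers(rng, HIGH_TAU_FRONTAL_RANGE)))
    for i in range(spec.n_non_high_ad):
        if i in plus_positions:
            designs.append((TIER_PLUS, False, _tau_plus_multipliers(rng)))
        else:
            designs.append((TIER_PLUSPLUS, False, _ad_plusplus_multipliers(rng, NON_HIGH_FRONTAL_RANGE)))
    for _ in range(spec.n_negative):
        designs.append((TIER_NEGATIVE, False, _negative_multipliers(rng)))

    cohort: list[tuple[VoxelGrid3D, TruthRecord]] = []
    for idx, (tier, high, mult) in enumerate(designs):
        scan_seed = int(rng.integers(0, 2**31 - 1))
        phantom = generate_phantom(
            atlas,
            PhantomSpec(
                multipliers=mult,
                noise_sd=spec.noise_sd,
                smoothing_fwhm_mm=spec.smoothing_fwhm_mm,
                seed=scan_seed,
            ),
        )
        cohort.append((phantom, TruthRecord(f"scan_{idx + 1:04d}", tier, high)))
    return cohort
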