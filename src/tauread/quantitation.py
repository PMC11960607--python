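"""Simplified AD-signature weighted SUVr quantitation.

SUVr = (weighted mean over a neocortical target) / (mean of a reference
region). The production quantitation pipeline this emulates uses a
voxel-weighted neocortical target with posterior regions weighted more
heavily and a white-matter-derived reference statistic; here the target
weights default to a labelled posterior:frontal = 2:1 stand-in over the atlas
cortical regions (user-replaceable by any nonnegative weight volume) and the
reference statistic is the arithmetic mean of the named reference region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .imaging_io import (
    CEREBELLUM,
    CORTICAL_REGION_SIDES,
    RegionAtlas,
    VoxelGrid3D,
    validate_grid_match,
)
from .visual_stratification import Tier

ELIGIBILITY_CUT = 1.10
HIGH_TAU_CUT = 1.46

_POSTERIOR_WEIGHT = 2.0
_FRONTAL_WEIGHT = 1.0


def default_weight_map(atlas: RegionAtlas) -> np.ndarray:
    """Synthetic stand-in target-weight volume over the atlas cortex.

    Posterior region-sides (temporal, occipital, parietal, precuneus) carry
    weight 2, frontal carries weight 1; weights are renormalised to sum to 1.
    """
    weights = np.zeros(atlas.shape, dtype=np.float64)
    for name in CORTICAL_REGION_SIDES:
        w = _FRONTAL_WEIGHT if name.startswith("frontal") else _POSTERIOR_WEIGHT
        weights[atlas.mask(name)] = w
    total = weights.sum()
    if total <= 0:
        raise ValueError("atlas has no cortical voxels to weight")
    return weights / total


@dataclass
class QuantConfig:
    """Quantitation parameters.

    ``target_weights`` must be a nonnegative 3-D grid summing to 1 over its
    support; ``None`` defers to :func:`default_weight_map` at compute time.
    """

    target_weights: Optional[np.ndarray] = None
    reference_region: str = CEREBELLUM
    eligibility_cut: float = ELIGIBILITY_CUT
    high_tau_cut: float = HIGH_TAU_CUT

    def __post_init__(self) -> None:
        if not self.eligibility_cut < self.high_tau_cut:
            raise ValueError("eligibility_cut must be below high_tau_cut")
        if self.target_weights is not None:
            w = np.asarray(self.target_weights, dtype=np.float64)
            if w.ndim != 3 or np.any(w < 0):
                raise ValueError("target_weights must be a nonnegative 3-D grid")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("target_weights must sum to 1")
            self.target_weights = w


@dataclass(frozen=True)
class SuvrResult:
    suvr: float
    eligible: bool
    high_tau_quant: bool
    reference_mean: float


def classify_quant(
    suvr: float, tier: Tier | None, config: QuantConfig | None = None
) -> tuple[bool, bool]:
    """Eligibility and high-tau status from a SUVr value.

    High tau is strictly ``suvr > high_tau_cut``. Eligibility is
    ``suvr >= eligibility_cut`` ("less than 1.10" is excluded, so the cut
    itself qualifies), except that advanced-pattern (tau-AD++) scans are
    eligible regardless of SUVr; that override never affects high-tau status.
    """
    if suvr <= 0:
        raise ValueError("suvr must be positive")
    config = config or QuantConfig()
    high_tau_quant = suvr > config.high_tau_cut
    eligible = suvr >= config.eligibility_cut or tier is Tier.PLUSPLUS
    return eligible, high_tau_quant


def compute_suvr(
    grid: VoxelGrid3D,
    atlas: RegionAtlas,
    config: QuantConfig | None = None,
    tier: Tier | None = None,
) -> SuvrResult:
    """Weighted-target SUVr against the mean of the reference region."""
    config = config or QuantConfig()
    validate_grid_match(grid, atlas)
    weights = (
        config.target_weights
        if config.target_weights is not None
        else default_weight_map(atlas)
    )
    if weights.shape != grid.shape:
        raise ValueError(
            f"weight grid misaligned: {weights.shape} vs scan {grid.shape}"
        )
    ref_vals = grid.values[atlas.mask(config.reference_region)]
    if ref_vals.size == 0:
        raise ValueError(f"reference region '{config.reference_region}' is empty")
    ref_mean = float(ref_vals.mean())
    if ref_mean == 0:
        raise ValueError("reference region mean is zero; SUVr undefined")
    suvr = float((weights * grid.values).sum() / ref_mean)
    eligible, high_tau_quant = classify_quant(suvr, tier, config)
    return SuvrResult(
        suvr=suvr,
        eligible=eligible,
        high_tau_quant=high_tau_quant,
        reference_mean=ref_mean,
    )
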