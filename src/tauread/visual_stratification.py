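"""Two-step visual stratification of tau PET scans.

The classifier automates the visual read: estimate the mean cerebellar count
(MCC), mark voxels above a threshold expressed as a multiple of the MCC, score
named cortical region-sides positive when they contain a sufficiently large
26-connected suprathreshold cluster, and apply a decision table.

Step 1 scores all twelve region-sides at 1.65x MCC and assigns a three-tier
label (tau-AD-negative / moderate / advanced). Step 2, applied only to
AD-pattern scans, rescores at 2.80x MCC; a scan is called high tau when either
frontal lobe is positive at that higher threshold. Because both thresholds are
multiples of the MCC, the whole procedure is invariant to a global intensity
rescaling of the scan.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .imaging_io import (
    CEREBELLUM,
    CORTICAL_REGION_SIDES,
    RegionAtlas,
    VoxelGrid3D,
    validate_grid_match,
)

STEP1_MULTIPLIER = 1.65
STEP2_MULTIPLIER = 2.80

#: 26-connectivity structuring element for cluster extraction.
_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


class Tier(str, Enum):
    """Three-tier visual read label."""

    NEGATIVE = "tau_ad_negative"
    PLUS = "tau_ad_plus"
    PLUSPLUS = "tau_ad_plusplus"


class MccMethod(str, Enum):
    MASK3D = "mask3d"
    SLICE2D = "slice2d"


@dataclass(frozen=True)
class MccEstimate:
    """Mean cerebellar count anchoring the visual thresholds."""

    value: float
    n_voxels: int
    method: MccMethod

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("MCC requires at least one cerebellar voxel")
        if not self.value > 0:
            raise ValueError(f"nonpositive MCC ({self.value}); scan looks corrupt")


def estimate_mcc(
    grid: VoxelGrid3D, atlas: RegionAtlas, method: MccMethod | str = MccMethod.MASK3D
) -> MccEstimate:
    """Estimate the mean cerebellar count.

    ``mask3d`` averages over the whole cerebellar ROI. ``slice2d`` mimics a
    manually drawn 2-D ROI by averaging over the single axial slice (last
    axis) containing the most cerebellar voxels.
    """
    method = MccMethod(method)
    validate_grid_match(grid, atlas)
    cb = atlas.mask(CEREBELLUM)
    if method is MccMethod.MASK3D:
        vals = grid.values[cb]
    else:
        per_slice = cb.sum(axis=(0, 1))
        z = int(np.argmax(per_slice))
        vals = grid.values[:, :, z][cb[:, :, z]]
    return MccEstimate(value=float(vals.mean()), n_voxels=int(vals.size), method=method)


def suprathreshold_map(
    grid: VoxelGrid3D, mcc: MccEstimate, multiplier: float
) -> np.ndarray:
    """Boolean map of voxels strictly above ``multiplier x MCC``."""
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return grid.values > multiplier * mcc.value


@dataclass
class RegionalScoreSet:
    """Per-region positivity at one threshold multiplier."""

    multiplier: float
    threshold_value: float
    scores: dict[str, bool]
    max_cluster_voxels: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "multiplier": self.multiplier,
            "threshold_value": self.threshold_value,
            "scores": dict(self.scores),
            "max_cluster_voxels": dict(self.max_cluster_voxels),
        }


RegionSpec = Mapping[str, Sequence[str]] | Sequence[str]


def _region_masks(atlas: RegionAtlas, regions: RegionSpec) -> dict[str, np.ndarray]:
    if isinstance(regions, Mapping):
        return {name: atlas.union_mask(parts) for name, parts in regions.items()}
    return {name: atlas.mask(name) for name in regions}


def score_regions(
    binary_map: np.ndarray,
    atlas: RegionAtlas,
    regions: RegionSpec,
    min_cluster_voxels: int = 5,
    *,
    multiplier: float = float("nan"),
    threshold_value: float = float("nan"),
) -> RegionalScoreSet:
    """Score regions positive on suprathreshold cluster extent.

    A region is positive iff some 26-connected component of ``binary_map``
    intersects the region mask in at least ``min_cluster_voxels`` voxels.
    ``regions`` is either a list of atlas region names or a mapping from a
    composite name to the atlas regions whose union defines it (used for the
    coarser step-2 scheme).
    """
    if min_cluster_voxels < 1:
        raise ValueError("min_cluster_voxels must be >= 1")
    masks = _region_masks(atlas, regions)
    if not masks:
        raise ValueError("regions must be nonempty")
    labeled, n_comp = ndimage.label(binary_map, structure=_CONNECTIVITY_26)
    scores: dict[str, bool] = {}
    max_cluster: dict[str, int] = {}
    for name, mask in masks.items():
        if n_comp == 0:
            largest = 0
        else:
            counts = np.bincount(labeled[mask], minlength=n_comp + 1)
            largest = int(counts[1:].max()) if counts.size > 1 else 0
        max_cluster[name] = largest
        scores[name] = largest >= min_cluster_voxels
    return RegionalScoreSet(
        multiplier=multiplier,
        threshold_value=threshold_value,
        scores=scores,
        max_cluster_voxels=max_cluster,
    )


# --- decision table -----------------------------------------------------------

_POSTERIOR_AD = ("lateral_posterior_temporal", "occipital", "parietal", "precuneus")
_ADVANCED = ("parietal", "precuneus", "frontal")


def _either_side(scores: Mapping[str, bool], regions: Sequence[str]) -> bool:
    return any(scores[f"{r}_{s}"] for r in regions for s in ("L", "R"))


@dataclass(frozen=True)
class DecisionRule:
    description: str
    condition: Callable[[Mapping[str, bool]], bool]
    tier: Tier


@dataclass(frozen=True)
class DecisionTable:
    """Ordered, total rule set mapping step-1 score patterns to tiers.

    Totality (every one of the 2^12 score patterns matches some rule) is
    verified by exhaustive enumeration at construction time.
    """

    name: str
    rules: tuple[DecisionRule, ...]

    def __post_init__(self) -> None:
        for pattern in itertools.product((False, True), repeat=len(CORTICAL_REGION_SIDES)):
            scores = dict(zip(CORTICAL_REGION_SIDES, pattern))
            if not any(rule.condition(scores) for rule in self.rules):
                raise ValueError(
                    f"decision table '{self.name}' is not total: no rule matches {scores}"
                )

    def classify(self, scores: Mapping[str, bool]) -> Tier:
        for rule in self.rules:
            if rule.condition(scores):
                return rule.tier
        raise AssertionError("unreachable: table verified total")

    @staticmethod
    def default() -> "DecisionTable":
        """Default 3-tier table.

        A scan is AD-pattern when any posterior region (lateral posterior
        temporal, occipital, parietal, precuneus) is positive on either side;
        AD-pattern scans with parietal, precuneus or frontal involvement are
        advanced (tau-AD++), otherwise moderate (tau-AD+).
        """
        return DecisionTable(
            name="default",
            rules=(
                DecisionRule(
                    "no posterior region positive -> tau_ad_negative",
                    lambda s: not _either_side(s, _POSTERIOR_AD),
                    Tier.NEGATIVE,
                ),
                DecisionRule(
                    "parietal/precuneus/frontal involvement -> tau_ad_plusplus",
                    lambda s: _either_side(s, _ADVANCED),
                    Tier.PLUSPLUS,
                ),
                DecisionRule(
                    "posterior-lateral pattern only -> tau_ad_plus",
                    lambda s: True,
                    Tier.PLUS,
                ),
            ),
        )


def classify_tier(step1: RegionalScoreSet, table: DecisionTable | None = None) -> Tier:
    """Assign the three-tier label from step-1 regional scores."""
    table = table or DecisionTable.default()
    missing = set(CORTICAL_REGION_SIDES) - set(step1.scores)
    if missing:
        raise ValueError(f"step-1 scores missing region-side(s): {sorted(missing)}")
    return table.classify(step1.scores)


# --- full two-step classifier ---------------------------------------------------

#: Step-2 scheme: four regions scored bilaterally, with "temporal" the union of
#: the two lateral temporal regions and "parietal" subsuming the precuneus.
STEP2_COMBINED_REGIONS: dict[str, tuple[str, ...]] = {
    f"{name}_{side}": parts
    for side in ("L", "R")
    for name, parts in {
        "temporal": ("lateral_anterior_temporal", "lateral_posterior_temporal"),
        "occipital": ("occipital",),
        "parietal": ("parietal", "precuneus"),
        "frontal": ("frontal",),
    }.items()
    for parts in [tuple(f"{p}_{side}" for p in parts)]
}


@dataclass(frozen=True)
class StratifyConfig:
    """Tunable parameters of the two-step classifier."""

    step1_multiplier: float = STEP1_MULTIPLIER
    step2_multiplier: float = STEP2_MULTIPLIER
    min_cluster_voxels: int = 5
    mcc_method: MccMethod = MccMethod.MASK3D
    decision_table: DecisionTable = field(default_factory=DecisionTable.default)
    step2_combined: bool = True

    def __post_init__(self) -> None:
        if self.step1_multiplier <= 0 or self.step2_multiplier <= 0:
            raise ValueError("threshold multipliers must be positive")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")

    def fingerprint(self) -> str:
        payload = {
            "step1_multiplier": self.step1_multiplier,
            "step2_multiplier": self.step2_multiplier,
            "min_cluster_voxels": self.min_cluster_voxels,
            "mcc_method": MccMethod(self.mcc_method).value,
            "decision_table": self.decision_table.name,
            "step2_combined": self.step2_combined,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class StratificationResult:
    """Outcome of the two-step visual stratification of one scan."""

    tier: Tier
    high_tau: bool
    step1: RegionalScoreSet
    step2: RegionalScoreSet | None
    mcc: MccEstimate
    config_fingerprint: str

    def __post_init__(self) -> None:
        if self.tier is Tier.NEGATIVE and (self.high_tau or self.step2 is not None):
            raise ValueError("tau-AD-negative scans cannot be high tau or carry step-2 scores")
        if self.high_tau:
            assert self.step2 is not None
            if not (self.step2.scores.get("frontal_L") or self.step2.scores.get("frontal_R")):
                raise ValueError("high_tau requires a positive frontal score in step 2")

    def to_dict(self) -> dict:
        return {
            "tier": self.tier.value,
            "high_tau": self.high_tau,
            "mcc": {
                "value": self.mcc.value,
                "n_voxels": self.mcc.n_voxels,
                "method": self.mcc.method.value,
            },
            "step1": self.step1.to_dict(),
            "step2": self.step2.to_dict() if self.step2 is not None else None,
            "config_fingerprint": self.config_fingerprint,
        }


def stratify_scan(
    grid: VoxelGrid3D, atlas: RegionAtlas, config: StratifyConfig | None = None
) -> StratificationResult:
    """Run the full two-step stratification on one scan.

    Step 1 thresholds at ``step1_multiplier x MCC`` and scores the twelve
    region-sides to assign the tier. Scans consistent with AD proceed to step
    2 at ``step2_multiplier x MCC``; the high-tau call is positivity of either
    frontal lobe at that threshold. The visual path never touches
    quantitation, so scans without a usable SUVr are still stratifiable.
    """
    config = config or StratifyConfig()
    validate_grid_match(grid, atlas)
    mcc = estimate_mcc(grid, atlas, config.mcc_method)

    step1_map = suprathreshold_map(grid, mcc, config.step1_multiplier)
    step1 = score_regions(
        step1_map,
        atlas,
        CORTICAL_REGION_SIDES,
        config.min_cluster_voxels,
        multiplier=config.step1_multiplier,
        threshold_value=config.step1_multiplier * mcc.value,
    )
    tier = classify_tier(step1, config.decision_table)

    step2 = None
    high_tau = False
    if tier is not Tier.NEGATIVE:
        regions: RegionSpec = (
            STEP2_COMBINED_REGIONS if config.step2_combined else CORTICAL_REGION_SIDES
        )
        step2_map = suprathreshold_map(grid, mcc, config.step2_multiplier)
        step2 = score_regions(
            step2_map,
            atlas,
            regions,
            config.min_cluster_voxels,
            multiplier=config.step2_multiplier,
            threshold_value=config.step2_multiplier * mcc.value,
        )
        high_tau = bool(step2.scores["frontal_L"] or step2.scores["frontal_R"])

    return StratificationResult(
        tier=tier,
        high_tau=high_tau,
        step1=step1,
        step2=step2,
        mcc=mcc,
        config_fingerprint=config.fingerprint(),
    )
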