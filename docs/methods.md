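# Methods

## The classifier

`tauread` automates a two-step threshold-and-region visual read of tau PET
scans. The scan and an integer label atlas must share one voxel grid (no
resampling or registration is performed; orientation is taken from the NIfTI
affine and all region logic runs in voxel space). The atlas names a cerebellar
reference region and six cortical regions per hemisphere.

**MCC.** The anchor of all thresholds is the mean cerebellar count. Two
estimators are provided: `mask3d` (default; arithmetic mean over the full
cerebellar ROI — reproducible and uses all available voxels) and `slice2d`
(mean over the single axial slice containing the most cerebellar voxels,
mimicking the manually drawn 2-D ROI a reader would place). A nonpositive MCC
is treated as a corrupt scan and rejected, since thresholds scale off it.

**Thresholding and regional scoring.** A voxel is suprathreshold when its
intensity is strictly greater than `multiplier × MCC`; both decision
thresholds (1.65 and 2.80) use strict `>` as printed. A region-side is scored
positive when a 26-connected component of the suprathreshold map intersects
the region mask in at least `min_cluster_voxels` voxels. The literal rule for
human readers is positivity "regardless of intensity or extent", i.e. a single
suprathreshold voxel; an automated classifier applying that literally is
hostage to single-voxel noise, so the default is `min_cluster_voxels = 5`
(about 40 mm³ at 2 mm voxels), configurable down to 1 to realise the literal
reading. Cluster labelling is scipy.ndimage with a full 3×3×3 structuring
element; the test suite checks it against an independent flood-fill
enumeration on small grids.

**Decision table.** The exact published three-tier rule text lives in a
supplement not reproduced here, so the tier assignment is a named, swappable
`DecisionTable` verified total over all 2^12 step-1 score patterns at
construction. The default table encodes the narrative rules: any positivity in
a posterior region (lateral posterior temporal, occipital, parietal,
precuneus) makes the scan AD-pattern; AD-pattern scans with parietal,
precuneus or frontal involvement are advanced (τAD++), otherwise moderate
(τAD+); everything else is τAD−. Frontal positivity alone is deliberately
*not* an AD pattern under this table.

**Step-2 granularity.** Step 1 scores six regions per side, step 2 four
(temporal, occipital, parietal, frontal). By default step-2 "temporal" is the
union of the two lateral temporal regions and step-2 "parietal" subsumes the
precuneus, giving 8 step-2 scores; `step2_combined=False` rescores the twelve
step-1 region-sides instead (useful for checking threshold nesting with
identical region definitions). Only the frontal scores feed the high-tau call;
the others are carried in the result but unused, matching the study protocol.

Consequences worth knowing: the classifier is exactly invariant to global
intensity scaling (MCC and thresholds scale together); every step-2-positive
region is step-1-positive under shared region definitions (2.80 > 1.65 with
the same strict inequality); and raising only frontal intensities can flip
high_tau from false to true but never the reverse.

## Quantitation (simplified)

SUVr = (Σ wᵢ·Iᵢ) / mean(reference region). The published quantitation uses a
voxel-weighted AD-signature neocortical target and a white-matter histogram
reference statistic whose algorithms are not part of this package's sources;
here the reference statistic is the arithmetic mean of the named reference
region (default cerebellum) and the default target weight map is a labelled
synthetic stand-in — posterior region-sides (temporal, occipital, parietal,
precuneus) at weight 2, frontal at weight 1, renormalised to sum to 1 — and is
user-replaceable by any nonnegative weight volume on the scan grid. Cut
semantics follow the printed wording exactly: high tau iff SUVr > 1.46
(strict); trial eligibility iff SUVr ≥ 1.10 ("less than 1.10" excluded, so the
cut itself qualifies) or the scan's visual tier is τAD++ — an override that
never affects high-tau status. The visual path has no dependency on
quantitation, so quantitation-failed scans remain stratifiable.

## Synthetic phantoms and cohorts

The phantom generator emulates only what the classifier consumes: regional
mean uptake relative to the cerebellum. Each cortical region-side is painted
at `multiplier × cerebellar_mean`, the cerebellum at `cerebellar_mean`,
background at 0.5× (so the 1.65× threshold never fires outside the brain
regions; real scans show similar sub-cerebellar contrast in non-target
tissue). The volume is then smoothed (isotropic Gaussian, FWHM in mm) and
degraded with additive i.i.d. Gaussian noise of the stated SD, all draws from
a single seeded generator. The default grid is 48³ at 2 mm — small enough for
seconds-scale tests, large enough that every region has hundreds of voxels.

Cohorts mirror the validation-study mix: 70 high-tau AD-pattern scans, 70
non-high AD-pattern scans, 20 tau-negative scans, with ~5% of the AD-pattern
pool carrying only the moderate pattern. Designed multiplier draws are:
frontal in (2.9, 3.6) for high-tau scans and (1.1, 2.6) for non-high AD scans;
posterior AD regions in (1.8, 3.0); τAD+ scans elevate only temporal/occipital
regions with parietal/precuneus/frontal in (0.9, 1.3); negative scans draw all
regions in (0.9, 1.2). No intensity distributions are published for real
scans; these margins are chosen once so that designed truth is unambiguous
after default smoothing. Because a moderate pattern has no frontal involvement
it cannot be visually high tau, so the moderate fraction is realised among the
non-high scans (count = round(fraction × AD-pattern total), capped).

What the phantoms do **not** emulate: anatomy, scanner point-spread beyond a
Gaussian, scatter/attenuation, inter-subject variability of the cerebellar
reference, and any calibrated mapping from multipliers to real SUVr. Passing
the recovery tests therefore demonstrates the decision logic is implemented
correctly and is robust to additive noise at the tested levels — not clinical
performance on real scans. In end-to-end study simulations the designed truth
(not the phantom SUVr) is the reference-standard column of the read matrix,
for the same reason.

## Agreement statistics

PPA, NPA and overall agreement are binomial proportions; CIs are Wilson score
intervals (statsmodels), with the bound pinned exactly to 0 (or 1) at 0 (or n)
successes. Report pooling follows the convention that reproduces published
"overall" rows: the pooled row sums per-reader contingencies and takes Wilson
intervals on the pooled counts; per-reader medians are also computed and
labelled separately (the two do not coincide in general). Scans without a
truth label are excluded from endpoint denominators (and counted) but retained
for κ.

Fleiss κ for two categories uses pooled category marginals for expected
agreement and mean per-scan pairwise agreement for observed agreement; its SE
is the Fleiss–Nee–Landis large-sample formula and the CI is normal-theory.
Published κ CIs computed under other variance estimators may differ in the
third decimal. The matrix form reduces to the agreement-split summary before
computing, so `fleiss_kappa` and `fleiss_kappa_from_summary` agree bit-for-bit
on any matrix realising a summary. Cohen κ (test–retest) uses the
Fleiss–Cohen–Everitt asymptotic variance; reported CI bounds are clipped to
[−1, 1], and identical constant rating vectors are defined as κ = 1 with
SE 0. Degenerate inputs (all calls one category) raise rather than return a
conventional value.

The reader-panel simulator draws each reader's call independently per scan
with fixed sensitivity/specificity; for that model the population Fleiss κ has
a closed form (`analytic_fleiss_kappa`) used as a parameter-recovery oracle in
tests, with 3×SE Monte-Carlo tolerance.

`tauread.reference_study` encodes the published summary counts of the
five-reader validation study and reconstructs one explicit 140×5 read matrix
consistent with *all* of them (per-reader TP/TN, agreement splits, per-reader
positive totals, majority contingency). Which particular scan received which
calls is synthetic — the statistics computed from the matrix depend only on
the counts, which is what makes the reconstruction faithful.

## Problem sizes and numerical choices

Default test and acceptance runs use 48³ grids, cohorts of 160 scans, and
simulated panels of 5 readers × 500–4000 scans; a full acceptance run takes a
few seconds on one CPU. Grid compatibility between scan and atlas is enforced
with an absolute affine tolerance of 1e-4. Majority reads require an odd panel
or an explicit tie rule. All randomness flows from explicit integer seeds; no
global RNG state is used anywhere.

## Known limitations

Geometric box phantoms only; no DICOM, registration or motion handling; binary
(high/non-high) κ only — no ordinal multi-tier κ; the default decision table
is an approximation of unpublished rule text and should be swapped if that
text is available; the simplified SUVr is not calibrated to any real
quantitation pipeline and must not be used to classify real scans.
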