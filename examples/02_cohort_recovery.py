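"""Generate a study-like synthetic cohort and measure designed-truth recovery.

A noiseless cohort (20 high-tau, 20 non-high AD-pattern, 6 negative scans)
is stratified scan by scan; with no noise the classifier should recover the
designed tier and high-tau label for every scan.
"""

from tauread import CohortSpec, build_synthetic_atlas, generate_cohort, stratify_scan

atlas = build_synthetic_atlas((48, 48, 48))
spec = CohortSpec(n_high_tau=20, n_non_high_ad=20, n_negative=6, seed=11)
cohort = generate_cohort(atlas, spec)

tier_hits = high_hits = 0
for grid, truth in cohort:
    result = stratify_scan(grid, atlas)
    tier_hits += result.tier.value == truth.tier
    high_hits += result.high_tau == truth.high_tau

n = len(cohort)
print(f"scans: {n}")
print(f"tier recovery:     {100 * tier_hits / n:.1f}%")
print(f"high-tau recovery: {100 * high_hits / n:.1f}%")
print(
    "\n100% is expected: without noise every designed multiplier sits safely on\n"
    "its side of the 1.65x / 2.80x MCC thresholds."
)
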