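"""Reader-study agreement statistics from the published summary counts.

Rebuilds the 140-scan x 5-reader read matrix consistent with the validation
study's printed counts, then computes per-reader and pooled PPA/NPA with
Wilson CIs, Fleiss kappa, majority-read endpoints, and the protocol success
criteria.
"""

from tauread import build_agreement_report, majority_contingency, ppa_npa
from tauread.reference_study import reader_study_read_matrix

matrix = reader_study_read_matrix()
report = build_agreement_report(matrix)

print("reader   PPA% (95% CI)          NPA% (95% CI)          overall%")
for reader, e in report.per_reader.items():
    print(
        f"{reader}  {e.ppa.point_pct:5.1f} ({e.ppa.ci_low_pct:.1f}-{e.ppa.ci_high_pct:.1f})"
        f"   {e.npa.point_pct:5.1f} ({e.npa.ci_low_pct:.1f}-{e.npa.ci_high_pct:.1f})"
        f"   {e.overall.point_pct:5.1f}"
    )
p = report.pooled
print(
    f"pooled    {p.ppa.point_pct:5.1f} ({p.ppa.ci_low_pct:.1f}-{p.ppa.ci_high_pct:.1f})"
    f"   {p.npa.point_pct:5.1f} ({p.npa.ci_low_pct:.1f}-{p.npa.ci_high_pct:.1f})"
    f"   {p.overall.point_pct:5.1f}"
)
k = report.fleiss
print(f"\nFleiss kappa: {k.statistic:.4f} (95% CI {k.ci_low:.4f}-{k.ci_high:.4f})")

maj = ppa_npa(majority_contingency(matrix))
print(
    f"majority read: PPA {maj.ppa.point_pct:.1f}% "
    f"({maj.ppa.ci_low_pct:.1f}-{maj.ppa.ci_high_pct:.1f}), "
    f"NPA {maj.npa.point_pct:.1f}% ({maj.npa.ci_low_pct:.1f}-{maj.npa.ci_high_pct:.1f})"
)
print(f"success criteria: PPA/NPA={report.success_ppa_npa}, Fleiss={report.success_fleiss}")
print(
    "\nPPA/NPA are sensitivity/specificity analogues against the quantitation\n"
    "reference standard; kappa is chance-corrected inter-reader agreement."
)
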