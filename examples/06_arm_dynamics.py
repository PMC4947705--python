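"""Compare arm-level biomarker dynamics on the %PFS axis.

Normalises every patient's series to log-ratio over their pre-treatment
baseline, interpolates at 10% PFS intervals and runs Mann-Whitney arm tests
per interval with the family-wise Bonferroni cut-off for a 15-biomarker
panel.
"""

import angiotraj as at

ds = at.generate_cohort(at.CohortConfig(seed=6))
res = at.interval_arm_comparison(ds, "Tie2")

print(res.table.to_string(index=False,
                          float_format=lambda v: f"{v:.3g}"))
print()
print(f"minimum p across bins: {res.min_p:.2g}")
print(f"Bonferroni cut-off (15 biomarkers x 10 bins): {res.bonferroni:.1g}")
print()
print(
    "Bins where the experimental arm's log-ratio sits below the standard"
    " arm's mark the on-treatment Tie2 suppression; a minimum p under the"
    " cut-off flags an arm difference that survives multiplicity"
    " correction over the whole panel."
)
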