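"""Simulate a two-arm trial cohort and inspect its longitudinal structure.

Builds the default synthetic cohort — 44 standard-chemotherapy and 48
chemotherapy-plus-VEGF-inhibitor patients, a Tie2/Ang1/Ca125 panel on the
trial visit calendar with 25% of on-treatment samples missing — and prints
its shape.
"""

import angiotraj as at

cfg = at.CohortConfig(seed=1)
ds = at.generate_cohort(cfg)

print(ds.summary())
print()
one = ds.patient_series(ds.patients["patient_id"].iloc[0], "Tie2")
print(one[["time_days", "concentration", "visit_label"]].to_string(index=False))
print()
print(
    "Each patient carries up to 10 timed samples per biomarker: two"
    " pre-treatment draws (negative days), cycle and month visits, and a"
    " progression draw for progressed patients. Concentrations follow a"
    " piecewise-linear log trajectory whose rebound marks progression."
)
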