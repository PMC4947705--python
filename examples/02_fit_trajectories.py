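"""Fit the hierarchical Bayesian changepoint model and compare arms.

Generates a cohort in which only the experimental arm's Tie2 declines and
rebounds (the standard arm drifts without an inflection), fits each arm
separately by MCMC and prints the group-level slope table plus the
Mann-Whitney contrast of patient-level slopes.
"""

import angiotraj as at

ds = at.generate_cohort(at.CohortConfig(seed=3))
posts = at.fit_by_arm(ds, "Tie2", at.McmcSettings(n_chains=2, n_draws=800,
                                                  n_warmup=800, seed=0))
table, comparison = at.summarize_posterior(posts)

slopes = table[table["parameter"].isin(["mu_beta", "mu_gamma"])]
print(slopes.to_string(index=False))
print()
for param, stats in comparison.items():
    print(f"{param}: experimental {stats['experimental_mean']:+.3f} vs "
          f"standard {stats['standard_mean']:+.3f} per month, "
          f"Mann-Whitney p = {stats['p']:.2g}")
print()
print(
    "mu_beta is the group-mean log-concentration slope before the"
    " inflection, mu_gamma after it (per month). A negative beta followed"
    " by a positive gamma in the experimental arm only signals a"
    " treatment-specific decline-and-rebound — the vascular-progression"
    " signature the alarm rules exploit."
)
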