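"""Posterior-predictive pseudo-trials: re-run the cohort 5000 times.

Fits Tie2 and Ca125 trajectories, then redraws each patient's trajectory
from their own posterior, imputes monthly (30 +/- 5 day) monitoring values
and evaluates the Tie2 50%-over-nadir rule, the GCIG Ca125 doubling rule
and their OR combination.
"""

import angiotraj as at

ds = at.generate_cohort(at.CohortConfig(seed=4))
mcmc = at.McmcSettings(n_chains=2, n_draws=600, n_warmup=600, seed=0)
posteriors = {b: at.fit_by_arm(ds, b, mcmc) for b in ("Tie2", "Ca125")}

cfg = at.PseudoTrialConfig(n_replicates=5000, seed=0)
rules = {
    "Tie2 +50% over nadir": [at.AlarmRule("Tie2", 0.5)],
    "Ca125 GCIG doubling": [at.AlarmRule("Ca125", 1.0)],
    "Ca125 OR Tie2": [at.AlarmRule("Ca125", 1.0), at.AlarmRule("Tie2", 0.5)],
}
for label, rs in rules.items():
    res = at.run_pseudo_trials(posteriors, ds, rs, cfg)
    ev = res.evaluation
    print(f"{label:22s} predicts {ev.prediction_rate:5.1f}% of progressed "
          f"patients at {ev.mean_prediction_time:.1f}% +/- "
          f"{ev.sd_prediction_time:.1f}% of PFS")
print()
print(
    "Each percentage averages per-patient alarm probabilities over 5000"
    " replicates per biomarker. The OR combination always predicts at"
    " least as many patients as its best component, and earlier."
)
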