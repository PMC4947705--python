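"""Posterior-predictive pseudo-trials for alarm-rule evaluation.

For every existing patient, trajectory parameters are drawn repeatedly from
that patient's own posterior (no new pseudo-patients are invented), monthly
monitoring values are imputed at 30 +/- 5 day intervals up to the patient's
progression date, and the alarm rules are run on each replicate as if the
values arrived sequentially in clinic.  Per-patient alarm probabilities are
averaged into a cohort prediction rate; an alternative majority-vote
aggregation (patient predicted iff at least half the replicates alarm) is
also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import LongitudinalDataset
from .hierarchical import HierarchicalPosterior
from .rules import AlarmRule, MonitoredSeries, RuleEvaluation, nadir_alarm_batch
from .trajectory import DAYS_PER_MONTH, PiecewiseLinearParams, evaluate_trajectory

__all__ = [
    "PseudoTrialConfig",
    "PseudoTrialResult",
    "sample_pseudo_trajectory",
    "impute_monthly",
    "run_pseudo_trials",
]


@dataclass(frozen=True)
class PseudoTrialConfig:
    """Replicate count and monitoring calendar for pseudo-trials."""

    n_replicates: int = 5000
    visit_interval_days: float = 30.0
    visit_jitter_days: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.visit_jitter_days < self.visit_interval_days:
            raise ValueError("jitter must be non-negative and below the interval")


@dataclass(frozen=True)
class PseudoTrialResult:
    """Cohort outcome of running one rule set over pseudo-trial replicates."""

    per_patient: pd.DataFrame          # patient_id, alarm_probability, mean_alarm_pct_pfs
    evaluation: RuleEvaluation         # rate = mean of per-patient probabilities
    evaluation_majority: RuleEvaluation  # patient predicted iff >= 50% replicates alarm
    rule_label: str
    n_replicates: int


def sample_pseudo_trajectory(
    posterior: HierarchicalPosterior, patient_id: str,
    replicate_seed: int | np.random.Generator,
) -> PiecewiseLinearParams:
    """One joint draw of a patient's trajectory parameters from the posterior.

    The draw picks a single MCMC iteration, so parameter correlations are
    preserved; it never falls back to group-level or prior sampling.
    """
    if patient_id not in posterior.patient_ids:
        raise KeyError(f"patient {patient_id!r} not in posterior ({posterior.arm} arm)")
    rng = (replicate_seed if isinstance(replicate_seed, np.random.Generator)
           else np.random.default_rng(replicate_seed))
    i = posterior.patient_ids.index(patient_id)
    c = rng.integers(posterior.n_chains)
    d = rng.integers(posterior.n_draws)
    pd_ = posterior.patient_draws
    return PiecewiseLinearParams(
        alpha=float(pd_["alpha"][c, d, i]),
        beta=float(pd_["beta"][c, d, i]),
        gamma=float(pd_["gamma"][c, d, i]),
        t_inflection=float(pd_["t_inflection"][c, d, i]),
        sigma=float(pd_["sigma"][c, d, i]),
    )


def monitoring_times(pfs_days: float, config: PseudoTrialConfig,
                     rng: np.random.Generator | None = None,
                     n_series: int = 1) -> np.ndarray:
    """Monthly visit times ``30k + U(-jitter, +jitter)`` up to ``pfs_days``.

    Returns an (n_series, n_visits) array; the visit count is fixed by the
    nominal calendar (``floor(pfs / interval)`` visits) so replicates align.
    """
    if pfs_days <= 0:
        raise ValueError("pfs_days must be positive")
    k = int(np.floor(pfs_days / config.visit_interval_days))
    nominal = config.visit_interval_days * np.arange(1, k + 1)
    if k == 0:
        return np.empty((n_series, 0))
    if config.visit_jitter_days > 0 and rng is not None:
        jitter = rng.uniform(-config.visit_jitter_days, config.visit_jitter_days,
                             size=(n_series, k))
    else:
        jitter = np.zeros((n_series, k))
    return np.minimum(nominal + jitter, pfs_days)


def impute_monthly(
    params: PiecewiseLinearParams, pfs_days: float,
    config: PseudoTrialConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> MonitoredSeries:
    """Impute one replicate's monthly monitoring series for one patient.

    Concentrations are posterior-predictive draws:
    ``exp(trajectory(t) + Normal(0, sigma))`` with the patient's drawn
    residual scale, at jittered monthly visit times.
    """
    config = config or PseudoTrialConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    t = monitoring_times(pfs_days, config, rng, n_series=1)[0]
    log_mean = evaluate_trajectory(params, t / DAYS_PER_MONTH) if t.size else np.empty(0)
    noise = (rng.normal(0.0, params.sigma, size=t.size)
             if params.sigma > 0 and t.size else 0.0)
    return MonitoredSeries(
        times_days=t, concentrations=np.exp(np.asarray(log_mean) + noise),
        pfs_days=float(pfs_days), progressed=True,
    )


def _replicate_alarms(
    posterior: HierarchicalPosterior, patient_id: str, pfs_days: float,
    rule: AlarmRule, config: PseudoTrialConfig, rng: np.random.Generator,
) -> np.ndarray:
    """Alarm time (days, NaN if none) for every replicate of one patient."""
    i = posterior.patient_ids.index(patient_id)
    r = config.n_replicates
    c = rng.integers(posterior.n_chains, size=r)
    d = rng.integers(posterior.n_draws, size=r)
    draws = posterior.patient_draws
    alpha = draws["alpha"][c, d, i]
    beta = draws["beta"][c, d, i]
    gamma = draws["gamma"][c, d, i]
    tau = draws["t_inflection"][c, d, i]
    sigma = draws["sigma"][c, d, i]

    t = monitoring_times(pfs_days, config, rng, n_series=r)   # (r, k)
    if t.shape[1] == 0:
        return np.full(r, np.nan)
    tm = t / DAYS_PER_MONTH
    log_mean = (
        alpha[:, None]
        + beta[:, None] * np.minimum(tm, tau[:, None])
        + gamma[:, None] * np.maximum(tm - tau[:, None], 0.0)
    )
    conc = np.exp(log_mean + sigma[:, None] * rng.standard_normal(t.shape))
    return nadir_alarm_batch(conc, t, rule.threshold_fraction,
                             require_confirmation=rule.require_confirmation)


def run_pseudo_trials(
    posteriors: dict[str, dict[str, HierarchicalPosterior]],
    dataset: LongitudinalDataset,
    rules: list[AlarmRule],
    config: PseudoTrialConfig | None = None,
) -> PseudoTrialResult:
    """Run alarm rules over posterior-predictive replicates of a cohort.

    ``posteriors`` maps biomarker name to per-arm posteriors (as returned by
    :func:`angiotraj.hierarchical.fit_by_arm`).  Multiple rules combine by
    OR within each replicate (earliest alarm wins).  Only progressed
    patients present in every requested posterior are monitored.
    """
    config = config or PseudoTrialConfig()
    if not rules:
        raise ValueError("need at least one alarm rule")
    for rule in rules:
        if rule.biomarker not in posteriors:
            raise KeyError(f"no fitted posterior for biomarker {rule.biomarker!r}")
    rng = np.random.default_rng(config.seed)
    patients = dataset.patients
    rows = []
    for _, pat in patients[patients["progressed"]].iterrows():
        pid, arm, pfs = pat["patient_id"], pat["arm"], float(pat["pfs_days"])
        alarm_by_rule = []
        covered = True
        for rule in rules:
            post = posteriors[rule.biomarker].get(arm)
            if post is None or pid not in post.patient_ids:
                covered = False
                break
            alarm_by_rule.append(
                _replicate_alarms(post, pid, pfs, rule, config, rng)
            )
        if not covered:
            continue
        stacked = np.vstack(alarm_by_rule)          # (n_rules, r)
        combined = np.nanmin(
            np.where(np.isnan(stacked), np.inf, stacked), axis=0
        )
        combined[np.isinf(combined)] = np.nan
        predicted = ~np.isnan(combined) & (combined <= pfs)
        prob = float(predicted.mean())
        pct = 100.0 * combined[predicted] / pfs
        rows.append(
            {
                "patient_id": pid,
                "arm": arm,
                "alarm_probability": prob,
                "mean_alarm_pct_pfs": float(pct.mean()) if pct.size else np.nan,
                "sd_alarm_pct_pfs": float(pct.std(ddof=1)) if pct.size > 1 else np.nan,
            }
        )
    if not rows:
        raise ValueError("no progressed patient is covered by all requested posteriors")
    per_patient = pd.DataFrame(rows)
    label = " OR ".join(
        f"{r.biomarker}+{int(round(100 * r.threshold_fraction))}%" for r in rules
    )
    thr = rules[0].threshold_fraction if len(rules) == 1 else np.nan

    alarmed = per_patient[per_patient["alarm_probability"] > 0]
    weights = alarmed["alarm_probability"].to_numpy()
    times = alarmed["mean_alarm_pct_pfs"].to_numpy()
    mean_t = float(np.average(times, weights=weights)) if len(alarmed) else np.nan
    sd_t = (
        float(np.sqrt(np.average((times - mean_t) ** 2, weights=weights)))
        if len(alarmed) > 1 else np.nan
    )
    evaluation = RuleEvaluation(
        threshold_fraction=thr,
        prediction_rate=float(per_patient["alarm_probability"].mean() * 100.0),
        mean_prediction_time=mean_t,
        sd_prediction_time=sd_t,
        n_predicted=int((per_patient["alarm_probability"] > 0.5).sum()),
        n_progressed=len(per_patient),
        biomarker=label,
    )
    majority = per_patient["alarm_probability"] >= 0.5
    maj_times = per_patient.loc[majority, "mean_alarm_pct_pfs"].to_numpy()
    evaluation_majority = RuleEvaluation(
        threshold_fraction=thr,
        prediction_rate=float(100.0 * majority.mean()),
        mean_prediction_time=float(np.mean(maj_times)) if maj_times.size else np.nan,
        sd_prediction_time=(float(np.std(maj_times, ddof=1))
                            if maj_times.size > 1 else np.nan),
        n_predicted=int(majority.sum()),
        n_progressed=len(per_patient),
        biomarker=label,
    )
    return PseudoTrialResult(
        per_patient=per_patient,
        evaluation=evaluation,
        evaluation_majority=evaluation_majority,
        rule_label=label,
        n_replicates=config.n_replicates,
    )
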