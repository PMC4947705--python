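"""Nadir-based progression-alarm rules and their cohort-level evaluation.

A rule tracks the running minimum (nadir) of a monitored concentration
series and alarms at the first visit whose value reaches
``nadir * (1 + threshold_fraction)``.  The GCIG-style Ca125 criterion is the
special case of a doubling from nadir (threshold 1.0); rules for different
biomarkers combine by OR (earliest alarm wins).  Alarms operate on the raw
concentration scale because a percent-over-nadir criterion is
scale-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AlarmRule",
    "MonitoredSeries",
    "RuleEvaluation",
    "nadir_alarm",
    "nadir_alarm_batch",
    "gcig_ca125_alarm",
    "combined_or_alarm",
    "evaluate_rule_over_cohort",
    "threshold_sweep",
]


@dataclass(frozen=True)
class AlarmRule:
    """Percent-over-nadir alarm for one biomarker.

    ``threshold_fraction=0.5`` alarms on a 50% rise above the running
    minimum; ``require_confirmation`` demands a second consecutive
    exceedance before alarming.
    """

    biomarker: str
    threshold_fraction: float
    require_confirmation: bool = False

    def __post_init__(self) -> None:
        if self.threshold_fraction <= 0:
            raise ValueError("threshold_fraction must be positive")


@dataclass(frozen=True)
class MonitoredSeries:
    """Sequentially monitored concentrations for one patient-biomarker."""

    times_days: np.ndarray
    concentrations: np.ndarray
    pfs_days: float
    progressed: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.times_days, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times_days", t)
        object.__setattr__(self, "concentrations", c)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must align")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("monitoring times must be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class RuleEvaluation:
    """Cohort summary of one rule at one threshold."""

    threshold_fraction: float
    prediction_rate: float        # % of progressed patients alarmed by progression
    mean_prediction_time: float   # mean %PFS at alarm among predicted
    sd_prediction_time: float
    n_predicted: int
    n_progressed: int
    biomarker: str = ""


def nadir_alarm(series: MonitoredSeries, rule: AlarmRule) -> float | None:
    """First monitoring time (days) at which the rule alarms, else ``None``.

    The nadir at step ``k`` is the minimum concentration over steps up to
    ``k``; the alarm fires at the first step whose value is at least
    ``nadir * (1 + threshold_fraction)``.  A point can never alarm against
    itself: for positive thresholds a new running minimum cannot exceed its
    own elevated cut-off, so a prior, lower point must exist.
    """
    c = series.concentrations
    if c.size == 0:
        return None
    nadir = np.minimum.accumulate(c)
    hit = c >= nadir * (1.0 + rule.threshold_fraction)
    if rule.require_confirmation:
        # alarm at the second of two consecutive exceedances
        hit = hit & np.concatenate([[False], hit[:-1]])
    if not hit.any():
        return None
    return float(series.times_days[int(np.argmax(hit))])


def nadir_alarm_batch(concentrations: np.ndarray, times_days: np.ndarray,
                      threshold_fraction: float,
                      require_confirmation: bool = False) -> np.ndarray:
    """Vectorised :func:`nadir_alarm` over replicate rows.

    ``concentrations`` is (n_series, n_visits); ``times_days`` either the
    same shape or a single shared visit vector.  Returns alarm times in
    days with ``NaN`` where no alarm fires.
    """
    c = np.asarray(concentrations, dtype=float)
    t = np.asarray(times_days, dtype=float)
    if c.ndim != 2:
        raise ValueError("concentrations must be 2-D (series x visits)")
    if c.shape[1] == 0:
        return np.full(c.shape[0], np.nan)
    nadir = np.minimum.accumulate(c, axis=1)
    hit = c >= nadir * (1.0 + threshold_fraction)
    if require_confirmation:
        prev = np.concatenate([np.zeros((c.shape[0], 1), bool), hit[:, :-1]], axis=1)
        hit = hit & prev
    any_hit = hit.any(axis=1)
    idx = np.argmax(hit, axis=1)
    if t.ndim == 1:
        alarm = t[idx].astype(float)
    else:
        alarm = t[np.arange(c.shape[0]), idx].astype(float)
    alarm[~any_hit] = np.nan
    return alarm


def gcig_ca125_alarm(series: MonitoredSeries,
                     require_confirmation: bool = False) -> float | None:
    """GCIG-style biochemical-progression alarm: doubling from the nadir."""
    return nadir_alarm(
        series,
        AlarmRule("Ca125", threshold_fraction=1.0,
                  require_confirmation=require_confirmation),
    )


def combined_or_alarm(alarm_times) -> float | None:
    """Earliest alarm among component rules; ``None`` if none fired."""
    components = list(alarm_times)
    if not components:
        raise ValueError("need at least one component alarm")
    alarms = [a for a in components if a is not None and not np.isnan(a)]
    return min(alarms) if alarms else None


def evaluate_rule_over_cohort(
    alarm_times: dict[str, float | None],
    pfs_days: dict[str, float],
    progressed: dict[str, bool] | None = None,
    threshold_fraction: float = np.nan,
    biomarker: str = "",
) -> RuleEvaluation:
    """Prediction rate and prediction quality of a rule over a cohort.

    A progressed patient counts as predicted when their alarm fires no later
    than progression; censored patients are excluded from the denominator.
    Prediction quality is the mean (and sd) of the alarm time as a
    percentage of each predicted patient's PFS.
    """
    progressed = progressed if progressed is not None else {p: True for p in pfs_days}
    prog = [p for p in pfs_days if progressed.get(p, False)]
    if not prog:
        raise ValueError("cohort contains no progressed patients")
    pct = []
    for p in prog:
        a = alarm_times.get(p)
        if a is not None and not np.isnan(a) and a <= pfs_days[p]:
            pct.append(100.0 * a / pfs_days[p])
    rate = 100.0 * len(pct) / len(prog)
    return RuleEvaluation(
        threshold_fraction=threshold_fraction,
        prediction_rate=rate,
        mean_prediction_time=float(np.mean(pct)) if pct else np.nan,
        sd_prediction_time=float(np.std(pct, ddof=1)) if len(pct) > 1 else np.nan,
        n_predicted=len(pct),
        n_progressed=len(prog),
        biomarker=biomarker,
    )


def threshold_sweep(
    cohort_series: dict[str, MonitoredSeries],
    thresholds,
    progressed: dict[str, bool] | None = None,
    biomarker: str = "",
    require_confirmation: bool = False,
) -> list[RuleEvaluation]:
    """Evaluate a grid of alarm thresholds on one cohort of series.

    Returns one :class:`RuleEvaluation` per threshold, suitable for plotting
    failure rate (1 - prediction rate) against mean prediction time.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold grid must be non-empty")
    out = []
    for thr in thresholds:
        rule = AlarmRule(biomarker or "biomarker", float(thr),
                         require_confirmation=require_confirmation)
        alarms = {pid: nadir_alarm(s, rule) for pid, s in cohort_series.items()}
        pfs = {pid: s.pfs_days for pid, s in cohort_series.items()}
        prog = progressed if progressed is not None else {
            pid: s.progressed for pid, s in cohort_series.items()
        }
        out.append(
            evaluate_rule_over_cohort(alarms, pfs, prog,
                                      threshold_fraction=float(thr),
                                      biomarker=biomarker)
        )
    return out


def evaluations_to_frame(evaluations: list[RuleEvaluation]) -> pd.DataFrame:
    """Rule evaluations as a flat table for CSV export."""
    return pd.DataFrame(
        [
            {
                "biomarker": e.biomarker,
                "threshold": e.threshold_fraction,
                "prediction_rate": e.prediction_rate,
                "mean_pct_pfs": e.mean_prediction_time,
                "sd_pct_pfs": e.sd_prediction_time,
                "n_predicted": e.n_predicted,
                "n_progressed": e.n_progressed,
            }
            for e in evaluations
        ]
    )
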