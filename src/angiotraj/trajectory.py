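"""Piecewise-linear changepoint trajectories on the log-concentration scale.

A patient's biomarker trajectory is modelled as a continuous piecewise-linear
function of time since treatment start: a pre-treatment level ``alpha``, a
slope ``beta`` up to the inflection time, and a slope ``gamma`` after it.
Concentrations are modelled on the natural-log scale so that back-transformed
values are always positive and slopes act multiplicatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DAYS_PER_MONTH",
    "PiecewiseLinearParams",
    "evaluate_trajectory",
    "log_likelihood",
    "composite_ang1_tie2",
]

#: Calendar average used to convert sample times in days to model months.
DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class PiecewiseLinearParams:
    """Parameters of one patient-biomarker trajectory.

    Attributes
    ----------
    alpha:
        Pre-treatment log-concentration (the level held for all ``t <= 0``).
    beta:
        Slope of the log-concentration before the inflection, per month.
    gamma:
        Slope after the inflection, per month.
    t_inflection:
        Inflection time in months from treatment start; must be positive.
    sigma:
        Residual standard deviation of the Gaussian measurement error on the
        log scale; must be positive.
    """

    alpha: float
    beta: float
    gamma: float
    t_inflection: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.t_inflection <= 0:
            raise ValueError("t_inflection must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def evaluate_trajectory(params: PiecewiseLinearParams, t):
    """Expected log-concentration at time ``t`` (months from treatment start).

    Computes ``alpha + beta * min(t, t_inflection) + S * gamma *
    (t - t_inflection)`` with ``S = 1`` when ``t > t_inflection`` and 0
    otherwise, which is continuous at the inflection.  Pre-treatment times
    (``t < 0``) are treated as replicates of the pre-treatment level and
    return ``alpha``.

    Accepts scalars or arrays; returns the matching shape.
    """
    t = np.asarray(t, dtype=float)
    t_eff = np.maximum(t, 0.0)
    tau = params.t_inflection
    value = (
        params.alpha
        + params.beta * np.minimum(t_eff, tau)
        + params.gamma * np.maximum(t_eff - tau, 0.0)
    )
    return value if value.ndim else float(value)


def log_likelihood(params: PiecewiseLinearParams, times, log_concentrations) -> float:
    """Gaussian log-likelihood of observed log-concentrations.

    Parameters
    ----------
    times:
        Observation times in months (pre-treatment times allowed).
    log_concentrations:
        Observed natural-log concentrations, same length as ``times``.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(log_concentrations, dtype=float)
    if times.size == 0:
        raise ValueError("measurements must be non-empty")
    if times.shape != y.shape:
        raise ValueError("times and log_concentrations must have equal length")
    if params.sigma <= 0:
        raise ValueError("sigma must be positive for a likelihood evaluation")
    resid = y - evaluate_trajectory(params, times)
    n = times.size
    return float(
        -0.5 * n * math.log(2.0 * math.pi)
        - n * math.log(params.sigma)
        - 0.5 * np.sum(resid**2) / params.sigma**2
    )


def composite_ang1_tie2(tie2_value, ang1_value):
    """Composite marker: Tie2 concentration times log2 of Ang1 concentration.

    Applied pointwise to time-matched Tie2/Ang1 pairs to build the derived
    ``Ang1xTie2`` series.  Ang1 must be strictly positive.
    """
    tie2 = np.asarray(tie2_value, dtype=float)
    ang1 = np.asarray(ang1_value, dtype=float)
    if np.any(ang1 <= 0):
        raise ValueError("Ang1 concentrations must be positive")
    value = tie2 * np.log2(ang1)
    return value if value.ndim else float(value)
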