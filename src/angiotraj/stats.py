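"""Descriptive cohort comparisons.

Log-ratio-over-baseline trajectories on the %PFS axis, per-interval
Mann-Whitney arm tests with a family-wise Bonferroni cut-off, and
complete-response versus stable-disease comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import LongitudinalDataset

__all__ = [
    "mann_whitney_u",
    "bonferroni_threshold",
    "NormalizedSeries",
    "to_normalized_series",
    "normalize_dataset",
    "IntervalComparison",
    "interval_arm_comparison",
    "response_comparison",
]

#: Largest per-group size for which the exact permutation null is enumerated.
EXACT_MAX_GROUP = 8


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns ``(U, p)`` where ``U`` counts pairs with ``x > y`` (ties half).
    For group sizes up to :data:`EXACT_MAX_GROUP` the p-value is exact,
    enumerating every assignment of the pooled values to the two groups;
    beyond that the normal approximation with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = float(np.sum((x[:, None] > y[None, :]) + 0.5 * (x[:, None] == y[None, :])))
    if n <= EXACT_MAX_GROUP and m <= EXACT_MAX_GROUP:
        pooled = np.concatenate([x, y])
        # U of a subset is its midrank sum minus n(n+1)/2, which equals the
        # pairwise greater-than count with ties counted half
        ranks = sps.rankdata(pooled)
        combos = np.array(list(combinations(range(n + m), n)))
        u_all = ranks[combos].sum(axis=1) - 0.5 * n * (n + 1)
        centre = 0.5 * n * m
        dev_obs = abs(u_obs - centre)
        p = float(np.mean(np.abs(u_all - centre) >= dev_obs - 1e-12))
        return u_obs, p
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def bonferroni_threshold(alpha: float = 0.05, n_biomarkers: int = 15,
                         n_bins: int = 10) -> float:
    """Family-wise significance cut-off ``alpha / (n_biomarkers * n_bins)``."""
    if n_biomarkers < 1 or n_bins < 1:
        raise ValueError("family sizes must be >= 1")
    return alpha / (n_biomarkers * n_bins)


@dataclass(frozen=True)
class NormalizedSeries:
    """One patient-biomarker series as (%PFS, log-ratio-over-baseline) pairs.

    The baseline is the arithmetic mean of the (up to two) pre-treatment
    concentrations; its own log-ratio is 0 and it anchors the series at
    %PFS = 0.  A sample drawn at progression lands at %PFS = 100.
    """

    patient_id: str
    biomarker: str
    baseline: float
    pct_pfs: np.ndarray
    log_ratio: np.ndarray


def to_normalized_series(times_days, concentrations, pfs_days: float,
                         patient_id: str = "", biomarker: str = "") -> NormalizedSeries:
    """Convert one measurement series to the %PFS / log-ratio scale."""
    t = np.asarray(times_days, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if pfs_days <= 0:
        raise ValueError("pfs_days must be positive")
    pre = t < 0
    if not pre.any():
        raise ValueError("series has no pre-treatment sample")
    baseline = float(np.mean(c[pre]))
    on = ~pre
    pct = np.concatenate([[0.0], 100.0 * t[on] / pfs_days])
    ratio = np.concatenate([[0.0], np.log(c[on] / baseline)])
    order = np.argsort(pct, kind="stable")
    return NormalizedSeries(patient_id, biomarker, baseline, pct[order], ratio[order])


def normalize_dataset(dataset: LongitudinalDataset, biomarker: str) -> list[NormalizedSeries]:
    """Normalized series for every patient carrying the biomarker."""
    out = []
    pfs = dataset.patients.set_index("patient_id")["pfs_days"]
    sub = dataset.samples[dataset.samples["biomarker"] == biomarker]
    if sub.empty:
        raise KeyError(f"biomarker {biomarker!r} not in dataset")
    for pid, grp in sub.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_days")
        out.append(
            to_normalized_series(
                grp["time_days"].to_numpy(), grp["concentration"].to_numpy(),
                float(pfs[pid]), patient_id=pid, biomarker=biomarker,
            )
        )
    return out


@dataclass(frozen=True)
class IntervalComparison:
    """Per-%PFS-bin arm comparison for one biomarker."""

    biomarker: str
    table: pd.DataFrame            # bin_low, bin_high, n_standard, n_experimental, U, p
    min_p: float
    bonferroni: float


def interval_arm_comparison(
    dataset: LongitudinalDataset,
    biomarker: str,
    interval_pct: float = 10.0,
    alpha: float = 0.05,
    n_biomarkers_family: int = 15,
) -> IntervalComparison:
    """Mann-Whitney arm contrast of log-ratios in each %PFS interval.

    Each patient contributes, per bin, their series linearly interpolated at
    the bin midpoint (no extrapolation beyond the patient's observed range);
    the reported Bonferroni threshold covers the full testing family of
    ``n_biomarkers_family`` biomarkers times the number of bins.
    """
    series = normalize_dataset(dataset, biomarker)
    arm_of = dataset.patients.set_index("patient_id")["arm"]
    edges = np.arange(0.0, 100.0 + 1e-9, interval_pct)
    mids = 0.5 * (edges[:-1] + edges[1:])
    n_bins = mids.size

    values: dict[int, dict[str, list[float]]] = {
        k: {"standard": [], "experimental": []} for k in range(n_bins)
    }
    for s in series:
        arm = str(arm_of[s.patient_id])
        lo, hi = s.pct_pfs.min(), s.pct_pfs.max()
        for k, mid in enumerate(mids):
            if lo <= mid <= hi and s.pct_pfs.size >= 2:
                values[k][arm].append(float(np.interp(mid, s.pct_pfs, s.log_ratio)))

    rows = []
    for k, mid in enumerate(mids):
        std, exp = values[k]["standard"], values[k]["experimental"]
        if not std or not exp:
            warnings.warn(
                f"{biomarker}: %PFS bin ({edges[k]:.0f},{edges[k + 1]:.0f}] lacks "
                "one arm and is skipped", stacklevel=2,
            )
            continue
        u, p = mann_whitney_u(exp, std)
        rows.append((edges[k], edges[k + 1], len(std), len(exp), u, p))
    table = pd.DataFrame(
        rows, columns=["bin_low", "bin_high", "n_standard", "n_experimental", "U", "p"]
    )
    if table.empty:
        raise ValueError(f"{biomarker}: no %PFS bin contains both arms")
    return IntervalComparison(
        biomarker=biomarker,
        table=table,
        min_p=float(table["p"].min()),
        bonferroni=bonferroni_threshold(alpha, n_biomarkers_family, n_bins),
    )


def response_comparison(
    dataset: LongitudinalDataset,
    response_labels: dict[str, str],
    assessment_day: float = 126.0,
    ca125_name: str = "Ca125",
    ca125_detectable_iu: float = 30.0,
) -> pd.DataFrame:
    """Complete-response vs stable-disease biomarker contrast.

    Partial responders are excluded.  Each patient contributes the
    on-treatment concentration nearest the response-assessment day (end of
    cycle 6 by default).  For the tumour-burden marker ``ca125_name``,
    patients whose pre-treatment level is below ``ca125_detectable_iu``
    (tumour not biochemically detectable) are excluded from that row.
    """
    keep = {pid for pid, lab in response_labels.items() if lab in ("CR", "SD")}
    s = dataset.samples
    rows = []
    for biomarker, sub in s.groupby("biomarker", sort=True):
        excluded: set[str] = set()
        if biomarker == ca125_name:
            pre = sub[sub["time_days"] < 0]
            base = pre.groupby("patient_id")["concentration"].mean()
            excluded = set(base[base < ca125_detectable_iu].index)
        groups: dict[str, list[float]] = {"CR": [], "SD": []}
        on = sub[(sub["time_days"] >= 0) & (~sub["is_progression_sample"])]
        for pid, g in on.groupby("patient_id"):
            if pid not in keep or pid in excluded:
                continue
            g = g.iloc[(g["time_days"] - assessment_day).abs().argsort()]
            groups[response_labels[pid]].append(float(g["concentration"].iloc[0]))
        if not groups["CR"] or not groups["SD"]:
            raise ValueError(
                f"{biomarker}: need at least one CR and one SD patient after exclusions"
            )
        u, p = mann_whitney_u(groups["CR"], groups["SD"])
        rows.append((biomarker, len(groups["CR"]), len(groups["SD"]), u, p))
    return pd.DataFrame(rows, columns=["biomarker", "n_cr", "n_sd", "U", "p"])
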