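"""Seeded synthetic trial cohorts with the longitudinal structure the
downstream analyses assume.

The generator emulates a two-arm ovarian-cancer trial sub-study: 44 patients
on standard chemotherapy and 48 on chemotherapy plus a VEGF inhibitor, each
sampled on a fixed visit calendar (two pre-treatment draws, cycle visits,
then 6/9/12-month visits and a progression draw), with per-patient
piecewise-linear log-concentration trajectories whose inflection point sits
at an arm-dependent fraction of the patient's progression-free interval.
Cross-biomarker correlation is induced by shared within-block latent factors
on the baseline level; scheduled on-treatment visits are dropped
independently to mimic missing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ARMS, PATIENT_COLUMNS, SAMPLE_COLUMNS, LongitudinalDataset
from .trajectory import DAYS_PER_MONTH, PiecewiseLinearParams, evaluate_trajectory

__all__ = [
    "DEFAULT_VISIT_GRID",
    "BiomarkerSpec",
    "CohortConfig",
    "default_panel",
    "sampling_schedule",
    "generate_patient_trajectory",
    "generate_cohort",
]

#: Reconstructed visit calendar in days from treatment start: two
#: pre-treatment draws, end of cycle-1 infusion, pre-cycle-2, pre-cycle-6,
#: end of cycle-6 infusion (3-weekly cycles), then 6/9/12-month visits.
DEFAULT_VISIT_GRID: tuple[tuple[str, float], ...] = (
    ("pretreatment_1", -14.0),
    ("pretreatment_2", -1.0),
    ("cycle1_end", 0.0),
    ("pre_cycle2", 21.0),
    ("pre_cycle6", 105.0),
    ("cycle6_end", 126.0),
    ("month6", 183.0),
    ("month9", 274.0),
    ("month12", 365.0),
)


@dataclass(frozen=True)
class BiomarkerSpec:
    """Generative description of one biomarker's trajectory family.

    Slopes are natural-log concentration per month; ``slope_*_mean_by_arm``
    map arm name to the group mean.  Arms listed in ``no_inflection_arms``
    get ``gamma`` bound to each patient's ``beta`` (a straight line), the
    default for the standard arm where no inflection is expected.
    ``correlation_block`` labels biomarkers whose baselines share a latent
    factor; the implied baseline correlation of two block members is the
    product of their ``factor_loading`` values.
    """

    name: str
    baseline_log_mean: float
    baseline_log_sd: float
    slope_before_mean_by_arm: dict[str, float]
    slope_after_mean_by_arm: dict[str, float]
    slope_sd: float
    inflection_fraction_mean: float = 0.5
    inflection_fraction_sd: float = 0.1
    noise_sd: float = 0.2
    correlation_block: str | None = None
    factor_loading: float = 0.8
    no_inflection_arms: tuple[str, ...] = ("standard",)

    def __post_init__(self) -> None:
        for sd in (self.baseline_log_sd, self.slope_sd, self.inflection_fraction_sd,
                   self.noise_sd):
            if sd < 0:
                raise ValueError(f"{self.name}: standard deviations must be >= 0")
        if not 0.0 < self.inflection_fraction_mean < 1.0:
            raise ValueError(f"{self.name}: inflection_fraction_mean must be in (0,1)")
        if not 0.0 <= self.factor_loading <= 1.0:
            raise ValueError(f"{self.name}: factor_loading must be in [0,1]")
        for arm_map in (self.slope_before_mean_by_arm, self.slope_after_mean_by_arm):
            unknown = set(arm_map) - set(ARMS)
            if unknown:
                raise ValueError(f"{self.name}: unknown arm(s) {sorted(unknown)}")


@dataclass(frozen=True)
class CohortConfig:
    """Shape and sampling plan of a synthetic cohort.

    ``pfs_distribution`` names a scipy-style family (``lognormal`` with
    ``median_days``/``log_sd``, or ``fixed`` with ``days``) for the
    progression-free interval; patients whose event falls beyond
    ``followup_days`` are censored there.  ``missing_rate`` is the
    independent per-visit probability that a scheduled non-pre-treatment,
    non-progression sample is absent.
    """

    n_standard: int = 44
    n_experimental: int = 48
    biomarkers: tuple[BiomarkerSpec, ...] = field(default_factory=tuple)
    pfs_distribution: dict = field(
        default_factory=lambda: {"name": "lognormal", "median_days": 540.0, "log_sd": 0.45}
    )
    missing_rate: float = 0.25
    followup_days: float = 730.0
    visit_grid: tuple[tuple[str, float], ...] = DEFAULT_VISIT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_standard < 1 or self.n_experimental < 1:
            raise ValueError("patient counts must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not self.biomarkers:
            object.__setattr__(self, "biomarkers", tuple(default_panel()))
        if len({b.name for b in self.biomarkers}) != len(self.biomarkers):
            raise ValueError("biomarker names must be unique")


def default_panel() -> list[BiomarkerSpec]:
    """Default three-marker panel: Tie2 and Ang1 (correlated angiopoietin
    block, experimental-arm inflection) plus Ca125 (tumour burden, inflected
    in both arms).

    Baselines are on plausible plasma scales (Tie2/Ang1 in pg/ml, Ca125 in
    IU/l); slopes are modest per-month log changes.
    """
    return [
        BiomarkerSpec(
            name="Tie2",
            baseline_log_mean=np.log(4000.0),
            baseline_log_sd=0.3,
            slope_before_mean_by_arm={"standard": -0.01, "experimental": -0.12},
            slope_after_mean_by_arm={"standard": -0.01, "experimental": 0.10},
            slope_sd=0.03,
            inflection_fraction_mean=0.55,
            inflection_fraction_sd=0.10,
            noise_sd=0.15,
            correlation_block="angiopoietin",
            factor_loading=0.8,
        ),
        BiomarkerSpec(
            name="Ang1",
            baseline_log_mean=np.log(9000.0),
            baseline_log_sd=0.4,
            slope_before_mean_by_arm={"standard": -0.01, "experimental": -0.08},
            slope_after_mean_by_arm={"standard": -0.01, "experimental": 0.06},
            slope_sd=0.03,
            inflection_fraction_mean=0.55,
            inflection_fraction_sd=0.10,
            noise_sd=0.18,
            correlation_block="angiopoietin",
            factor_loading=0.8,
        ),
        BiomarkerSpec(
            name="Ca125",
            baseline_log_mean=np.log(250.0),
            baseline_log_sd=1.0,
            slope_before_mean_by_arm={"standard": -0.45, "experimental": -0.45},
            slope_after_mean_by_arm={"standard": 0.25, "experimental": 0.25},
            slope_sd=0.10,
            inflection_fraction_mean=0.50,
            inflection_fraction_sd=0.10,
            noise_sd=0.25,
            correlation_block=None,
            no_inflection_arms=(),
        ),
    ]


def sampling_schedule(pfs_days: float, config: CohortConfig | None = None,
                      progressed: bool = True) -> list[tuple[str, float]]:
    """Visit grid truncated at a patient's progression-free interval.

    Returns ``(visit_label, time_days)`` pairs: every grid visit strictly
    before ``pfs_days``, plus a terminal ``"progression"`` visit at
    ``pfs_days`` when the patient progressed.
    """
    if pfs_days <= 0:
        raise ValueError("pfs_days must be positive")
    grid = (config.visit_grid if config is not None else DEFAULT_VISIT_GRID)
    schedule = [(label, day) for label, day in grid if day < pfs_days]
    if progressed:
        schedule.append(("progression", float(pfs_days)))
    return schedule


def generate_patient_trajectory(
    params: PiecewiseLinearParams,
    schedule_days,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Concentrations at the scheduled visits for one patient-biomarker.

    ``exp(piecewise-linear log-trajectory + Gaussian noise)``; pre-treatment
    visits sit at the ``alpha`` level.  Deterministic given the seed.
    """
    days = np.asarray(schedule_days, dtype=float)
    if days.size == 0:
        raise ValueError("schedule must be non-empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    log_mean = evaluate_trajectory(params, days / DAYS_PER_MONTH)
    noise = rng.normal(0.0, noise_sd, size=days.size) if noise_sd > 0 else 0.0
    return np.exp(log_mean + noise)


def _draw_pfs(config: CohortConfig, rng: np.random.Generator, n: int):
    dist = dict(config.pfs_distribution)
    name = dist.pop("name", "lognormal")
    if name == "lognormal":
        median = float(dist.get("median_days", 540.0))
        log_sd = float(dist.get("log_sd", 0.45))
        event = np.exp(rng.normal(np.log(median), log_sd, size=n))
    elif name == "fixed":
        event = np.full(n, float(dist["days"]))
    else:
        raise ValueError(f"unknown pfs_distribution {name!r}")
    progressed = event <= config.followup_days
    pfs = np.minimum(event, config.followup_days)
    # keep at least one on-treatment visit possible
    pfs = np.maximum(pfs, 1.0)
    return pfs, progressed


def generate_cohort(config: CohortConfig) -> LongitudinalDataset:
    """Draw a full synthetic cohort, reproducibly from ``config.seed``.

    Patient-level trajectory parameters come from the per-biomarker
    hierarchies in ``config.biomarkers``; baseline levels of biomarkers in
    the same ``correlation_block`` share a standard-normal latent factor.
    Pre-treatment and progression visits are never dropped by missingness.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_standard + config.n_experimental
    arms = ["standard"] * config.n_standard + ["experimental"] * config.n_experimental
    ids = [f"P{i + 1:03d}" for i in range(n_total)]

    pfs, progressed = _draw_pfs(config, rng, n_total)
    blocks = sorted({b.correlation_block for b in config.biomarkers
                     if b.correlation_block is not None})
    latent = {blk: rng.standard_normal(n_total) for blk in blocks}

    sample_rows: list[tuple] = []
    for i, (pid, arm) in enumerate(zip(ids, arms)):
        schedule = sampling_schedule(pfs[i], config, progressed=bool(progressed[i]))
        labels = np.array([lab for lab, _ in schedule])
        days = np.array([d for _, d in schedule])
        droppable = (days >= 0) & (labels != "progression")
        keep = ~droppable | (rng.random(days.size) >= config.missing_rate)
        for spec in config.biomarkers:
            lam = spec.factor_loading if spec.correlation_block else 0.0
            z = latent[spec.correlation_block][i] if spec.correlation_block else 0.0
            resid = rng.standard_normal()
            alpha = spec.baseline_log_mean + spec.baseline_log_sd * (
                lam * z + np.sqrt(max(1.0 - lam**2, 0.0)) * resid
            )
            beta = rng.normal(spec.slope_before_mean_by_arm.get(arm, 0.0), spec.slope_sd)
            if arm in spec.no_inflection_arms:
                gamma = beta
            else:
                gamma = rng.normal(spec.slope_after_mean_by_arm.get(arm, 0.0), spec.slope_sd)
            frac = np.clip(
                rng.normal(spec.inflection_fraction_mean, spec.inflection_fraction_sd),
                0.05, 0.95,
            )
            params = PiecewiseLinearParams(
                alpha=float(alpha), beta=float(beta), gamma=float(gamma),
                t_inflection=float(frac * pfs[i] / DAYS_PER_MONTH),
                sigma=spec.noise_sd,
            )
            conc = generate_patient_trajectory(params, days, spec.noise_sd, rng)
            for k in np.flatnonzero(keep):
                sample_rows.append(
                    (pid, arm, spec.name, float(days[k]), float(conc[k]),
                     str(labels[k]), labels[k] == "progression")
                )

    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS).astype(
        {"patient_id": str, "arm": str, "biomarker": str, "time_days": float,
         "concentration": float, "visit_label": str, "is_progression_sample": bool}
    )
    samples = samples.sort_values(
        ["patient_id", "biomarker", "time_days"], kind="stable"
    ).reset_index(drop=True)
    patients = pd.DataFrame(
        {"patient_id": ids, "arm": arms, "pfs_days": pfs.astype(float),
         "progressed": progressed.astype(bool)},
        columns=PATIENT_COLUMNS,
    )
    return LongitudinalDataset(samples, patients)
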