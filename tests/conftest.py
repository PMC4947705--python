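import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import angiotraj as at

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_spec(**kw):
    """One-biomarker generative spec with sensible test defaults."""
    base = dict(
        name="Tie2",
        baseline_log_mean=8.0,
        baseline_log_sd=0.3,
        slope_before_mean_by_arm={"standard": -3.4, "experimental": -3.4},
        slope_after_mean_by_arm={"standard": 0.9, "experimental": 0.9},
        slope_sd=0.5,
        inflection_fraction_mean=0.5,
        inflection_fraction_sd=0.1,
        noise_sd=0.2,
        no_inflection_arms=(),
    )
    base.update(kw)
    return at.BiomarkerSpec(**base)


def make_cohort(n_std=10, n_exp=10, seed=0, **spec_kw):
    cfg = at.CohortConfig(
        n_std, n_exp, (make_spec(**spec_kw),),
        {"name": "lognormal", "median_days": 300.0, "log_sd": 0.3},
        missing_rate=0.0, followup_days=10000.0, seed=seed,
    )
    return at.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """10+10 patients, one biomarker, no missingness, everyone progresses."""
    return make_cohort()


@pytest.fixture(scope="session")
def panel_cohort():
    """Default three-marker panel at trial arm sizes with missing visits."""
    return at.generate_cohort(at.CohortConfig(seed=11))


def degenerate_posterior(params: at.PiecewiseLinearParams, patient_ids, arm="experimental",
                         biomarker="Tie2", n_chains=1, n_draws=50):
    """Posterior whose every draw equals the given parameter point."""
    n = len(patient_ids)
    shape = (n_chains, n_draws, n)
    patient_draws = {
        "alpha": np.full(shape, params.alpha),
        "beta": np.full(shape, params.beta),
        "gamma": np.full(shape, params.gamma),
        "t_inflection": np.full(shape, params.t_inflection),
        "sigma": np.full(shape, params.sigma),
    }
    group_draws = {
        "mu_beta": np.full(shape[:2], params.beta),
        "mu_gamma": np.full(shape[:2], params.gamma),
        "sd_beta": np.full(shape[:2], 1e-6),
        "sd_gamma": np.full(shape[:2], 1e-6),
    }
    return at.HierarchicalPosterior(
        arm=arm, biomarker=biomarker, patient_ids=list(patient_ids),
        patient_draws=patient_draws, group_draws=group_draws,
        n_chains=n_chains, n_draws=n_draws, seed=0,
    )
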