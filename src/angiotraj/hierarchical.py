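"""Hierarchical Bayesian inference for piecewise-linear biomarker trajectories.

Model (per treatment arm, on the natural-log concentration scale, time in
months from treatment start)::

    y_ij ~ Normal(f(t_ij; alpha_i, beta_i, gamma_i, tau_i), sigma_i^2)
    f(t)  = alpha + beta * min(t+, tau) + gamma * max(t+ - tau, 0),  t+ = max(t, 0)

    alpha_i ~ Normal(0, 10^2)                      (vague; identified by the
                                                    pre-treatment replicates)
    beta_i  ~ Normal(mu_beta,  sd_beta^2)
    gamma_i ~ Normal(mu_gamma, sd_gamma^2)
    tau_i   ~ Uniform(0, T_i)                      (T_i = patient's last visit)
    sigma_i ~ HalfNormal(2)
    mu_beta, mu_gamma ~ Normal(0, 10^2)
    sd_beta, sd_gamma ~ HalfNormal(5)

Inference is Metropolis-within-Gibbs, vectorised across patients: the linear
block (alpha, beta, gamma) and the group means are conjugate Gaussian
updates; the changepoints, residual scales and between-patient scales take
adaptive random-walk steps tuned during warm-up.  Group-level location and
spread of the changepoint are reported as derived quantities (posterior
moments of the patient-level draws) rather than extra model parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ARMS, LongitudinalDataset
from .stats import mann_whitney_u
from .trajectory import DAYS_PER_MONTH

__all__ = [
    "McmcSettings",
    "HierarchicalPosterior",
    "fit_hierarchical",
    "fit_by_arm",
    "summarize_posterior",
]

GROUP_PARAMS = ("mu_beta", "mu_gamma", "sd_beta", "sd_gamma")
PATIENT_PARAMS = ("alpha", "beta", "gamma", "t_inflection", "sigma")


@dataclass(frozen=True)
class McmcSettings:
    """Sampler configuration.

    Priors are weakly informative and scale-free by default; all are
    configurable.  ``seed`` drives every chain (chains get independent
    spawned streams).
    """

    n_chains: int = 2
    n_draws: int = 1000
    n_warmup: int = 1000
    seed: int = 0
    prior_alpha_sd: float = 10.0
    prior_group_mean_sd: float = 10.0
    prior_between_sd_scale: float = 5.0
    prior_sigma_scale: float = 2.0
    rhat_warn: float = 1.1

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_draws < 1 or self.n_warmup < 0:
            raise ValueError("invalid MCMC settings")


@dataclass
class HierarchicalPosterior:
    """MCMC draws for one arm's hierarchical trajectory model.

    ``patient_draws`` maps each of :data:`PATIENT_PARAMS` to an array of
    shape ``(n_chains, n_draws, n_patients)``; ``group_draws`` maps each of
    :data:`GROUP_PARAMS` plus the derived ``mu_t_inflection`` /
    ``sd_t_inflection`` to ``(n_chains, n_draws)``.  Times are months.
    """

    arm: str
    biomarker: str
    patient_ids: list[str]
    patient_draws: dict[str, np.ndarray]
    group_draws: dict[str, np.ndarray]
    n_chains: int
    n_draws: int
    seed: int
    diagnostics: dict[str, float] = field(default_factory=dict)

    # -- summaries ------------------------------------------------------
    def patient_posterior_means(self, param: str) -> pd.Series:
        draws = self.patient_draws[param]
        return pd.Series(
            draws.reshape(-1, draws.shape[-1]).mean(axis=0),
            index=self.patient_ids, name=param,
        )

    def group_summary(self) -> pd.DataFrame:
        rows = []
        for name, draws in self.group_draws.items():
            flat = draws.ravel()
            rows.append(
                {
                    "parameter": name,
                    "arm": self.arm,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": np.quantile(flat, 0.025),
                    "q97.5": np.quantile(flat, 0.975),
                    "rhat": self.diagnostics.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def converged(self, threshold: float = 1.1) -> bool:
        return all(r <= threshold for r in self.diagnostics.values() if np.isfinite(r))


def _prepare_arrays(dataset: LongitudinalDataset, biomarker: str, arm: str,
                    min_post: int = 3):
    """Padded (y, t_months, mask) arrays for every usable patient in an arm."""
    sub = dataset.samples[dataset.samples["biomarker"] == biomarker]
    if sub.empty:
        raise KeyError(f"biomarker {biomarker!r} not in dataset")
    pats = dataset.patients[dataset.patients["arm"] == arm]
    if pats.empty:
        raise ValueError(f"no patients in arm {arm!r}")
    series, dropped = [], []
    for pid in pats["patient_id"]:
        g = sub[sub["patient_id"] == pid].sort_values("time_days")
        if g.empty:
            continue
        t = g["time_days"].to_numpy(dtype=float) / DAYS_PER_MONTH
        if np.sum(t >= 0) < min_post:
            dropped.append(pid)
            continue
        series.append((pid, t, np.log(g["concentration"].to_numpy(dtype=float))))
    if dropped:
        warnings.warn(
            f"{biomarker}/{arm}: {len(dropped)} patient(s) with fewer than "
            f"{min_post} post-treatment samples excluded", stacklevel=3,
        )
    if len(series) < 2:
        raise ValueError(
            f"{biomarker}/{arm}: need >= 2 patients with >= {min_post} "
            "post-treatment observations"
        )
    n = len(series)
    vmax = max(t.size for _, t, _ in series)
    t_pad = np.zeros((n, vmax))
    y_pad = np.zeros((n, vmax))
    mask = np.zeros((n, vmax))
    for i, (_, t, y) in enumerate(series):
        t_pad[i, : t.size] = t
        y_pad[i, : t.size] = y
        mask[i, : t.size] = 1.0
    ids = [pid for pid, _, _ in series]
    return ids, y_pad, t_pad, mask


def _ssq(y, t_eff, mask, alpha, beta, gamma, tau):
    """Per-patient weighted residual sum of squares for given changepoints."""
    mean = (
        alpha[:, None]
        + beta[:, None] * np.minimum(t_eff, tau[:, None])
        + gamma[:, None] * np.maximum(t_eff - tau[:, None], 0.0)
    )
    return np.sum(mask * (y - mean) ** 2, axis=1)


def _init_state(y, t, mask, t_last, rng):
    n = y.shape[0]
    pre = (t < 0) & (mask > 0)
    alpha = np.where(pre.any(1), np.sum(y * pre, 1) / np.maximum(pre.sum(1), 1),
                     (y * mask).sum(1) / mask.sum(1))
    tau = 0.5 * t_last * np.exp(0.2 * rng.standard_normal(n))
    tau = np.clip(tau, 0.05 * t_last, 0.95 * t_last)
    beta = np.zeros(n)
    gamma = np.zeros(n)
    t_eff = np.maximum(t, 0.0)
    for i in range(n):
        obs = mask[i] > 0
        ti, yi = t_eff[i, obs], y[i, obs]
        early = ti <= tau[i]
        if early.sum() >= 2 and np.ptp(ti[early]) > 0:
            beta[i] = np.polyfit(ti[early], yi[early], 1)[0]
        late = ti >= tau[i]
        if late.sum() >= 2 and np.ptp(ti[late]) > 0:
            gamma[i] = np.polyfit(ti[late], yi[late], 1)[0]
    beta += 0.1 * rng.standard_normal(n)
    gamma += 0.1 * rng.standard_normal(n)
    sigma = np.full(n, 0.3) * np.exp(0.1 * rng.standard_normal(n))
    return alpha, beta, gamma, tau, sigma


def _run_chain(y, t, mask, settings: McmcSettings, rng: np.random.Generator):
    n, _ = y.shape
    t_eff = np.maximum(t, 0.0)
    n_obs = mask.sum(axis=1)
    t_last = t_eff.max(axis=1)
    alpha, beta, gamma, tau, sigma = _init_state(y, t, mask, t_last, rng)
    mu_beta = beta.mean()
    mu_gamma = gamma.mean()
    sd_beta = max(beta.std(), 0.1)
    sd_gamma = max(gamma.std(), 0.1)

    # adaptive random-walk scales (log) and acceptance counters
    step_tau = np.log(0.1 * np.maximum(t_last, 1e-3))
    step_sig = np.full(n, np.log(0.3))
    step_sd = {"sd_beta": np.log(0.3), "sd_gamma": np.log(0.3)}
    acc = {"tau": np.zeros(n), "sig": np.zeros(n), "sd_beta": 0.0, "sd_gamma": 0.0}
    window = 50

    a_prec = 1.0 / settings.prior_alpha_sd**2
    g_prec = 1.0 / settings.prior_group_mean_sd**2
    hn_sd = settings.prior_between_sd_scale
    hn_sig = settings.prior_sigma_scale

    total = settings.n_warmup + settings.n_draws
    out_pat = {p: np.empty((settings.n_draws, n)) for p in PATIENT_PARAMS}
    out_grp = {p: np.empty(settings.n_draws) for p in GROUP_PARAMS}

    eye3 = np.eye(3)
    for it in range(total):
        inv_s2 = 1.0 / sigma**2

        # --- conjugate linear block (alpha_i, beta_i, gamma_i) ---------
        x1 = np.minimum(t_eff, tau[:, None])
        x2 = np.maximum(t_eff - tau[:, None], 0.0)
        X = np.stack([np.broadcast_to(mask, x1.shape), x1 * mask, x2 * mask], axis=2)
        w = mask * inv_s2[:, None]
        XtX = np.einsum("nv,nvi,nvj->nij", w, X, X)
        Xty = np.einsum("nv,nvi,nv->ni", w, X, y)
        p0 = np.array([a_prec, 1.0 / sd_beta**2, 1.0 / sd_gamma**2])
        m0 = np.array([0.0, mu_beta, mu_gamma])
        A = XtX + p0 * eye3
        b = Xty + p0 * m0
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b[..., None])[..., 0]
        z = rng.standard_normal((n, 3, 1))
        theta = mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), z)[..., 0]
        alpha, beta, gamma = theta[:, 0], theta[:, 1], theta[:, 2]

        # --- changepoint Metropolis (two sweeps per iteration) ---------
        ss_cur = _ssq(y, t_eff, mask, alpha, beta, gamma, tau)
        for _ in range(2):
            prop = tau + np.exp(step_tau) * rng.standard_normal(n)
            valid = (prop > 0.0) & (prop < t_last)
            ss_prop = _ssq(y, t_eff, mask, alpha, beta, gamma,
                           np.where(valid, prop, tau))
            log_r = -0.5 * (ss_prop - ss_cur) * inv_s2
            take = valid & (np.log(rng.random(n)) < log_r)
            tau = np.where(take, prop, tau)
            ss_cur = np.where(take, ss_prop, ss_cur)
            acc["tau"] += take

        # --- residual scale Metropolis ---------------------------------
        prop_log = np.log(sigma) + np.exp(step_sig) * rng.standard_normal(n)
        sig_p = np.exp(prop_log)
        def _sig_logpost(s):
            return (-(n_obs - 1.0) * np.log(s) - 0.5 * ss_cur / s**2
                    - 0.5 * s**2 / hn_sig**2)
        take = np.log(rng.random(n)) < _sig_logpost(sig_p) - _sig_logpost(sigma)
        sigma = np.where(take, sig_p, sigma)
        # numerical floor so exactly noise-free data cannot overflow 1/sigma^2
        sigma = np.maximum(sigma, 1e-6)
        acc["sig"] += take

        # --- group means (conjugate) -----------------------------------
        for vec, which in ((beta, "beta"), (gamma, "gamma")):
            sd = sd_beta if which == "beta" else sd_gamma
            prec = n / sd**2 + g_prec
            m = (vec.sum() / sd**2) / prec
            draw = m + rng.standard_normal() / np.sqrt(prec)
            if which == "beta":
                mu_beta = draw
            else:
                mu_gamma = draw

        # --- between-patient scales (random walk) ----------------------
        for which, vec, mu in (("sd_beta", beta, mu_beta), ("sd_gamma", gamma, mu_gamma)):
            cur = sd_beta if which == "sd_beta" else sd_gamma
            ssd = np.sum((vec - mu) ** 2)
            prop = cur * np.exp(np.exp(step_sd[which]) * rng.standard_normal())
            def _sd_logpost(s):
                return -(n - 1.0) * np.log(s) - 0.5 * ssd / s**2 - 0.5 * s**2 / hn_sd**2
            if np.log(rng.random()) < _sd_logpost(prop) - _sd_logpost(cur):
                if which == "sd_beta":
                    sd_beta = prop
                else:
                    sd_gamma = prop
                acc[which] += 1.0

        # --- warm-up adaptation ----------------------------------------
        if it < settings.n_warmup and (it + 1) % window == 0:
            step_tau += 0.5 * (acc["tau"] / (2 * window) - 0.44)
            step_sig += 0.5 * (acc["sig"] / window - 0.44)
            for key in ("sd_beta", "sd_gamma"):
                step_sd[key] += 0.5 * (acc[key] / window - 0.44)
            acc = {"tau": np.zeros(n), "sig": np.zeros(n),
                   "sd_beta": 0.0, "sd_gamma": 0.0}

        if it >= settings.n_warmup:
            k = it - settings.n_warmup
            out_pat["alpha"][k] = alpha
            out_pat["beta"][k] = beta
            out_pat["gamma"][k] = gamma
            out_pat["t_inflection"][k] = tau
            out_pat["sigma"][k] = sigma
            out_grp["mu_beta"][k] = mu_beta
            out_grp["mu_gamma"][k] = mu_gamma
            out_grp["sd_beta"][k] = sd_beta
            out_grp["sd_gamma"][k] = sd_gamma
    return out_pat, out_grp


def _rhat(draws: np.ndarray) -> float:
    """Rank-normalised split potential-scale-reduction, (n_chains, n_draws)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(draws))


def fit_hierarchical(
    dataset: LongitudinalDataset,
    biomarker: str,
    mcmc: McmcSettings | None = None,
    arm: str = "experimental",
) -> HierarchicalPosterior:
    """Fit the hierarchical changepoint model to one arm of one biomarker.

    Requires at least two patients with three or more post-treatment
    observations; patients below that are excluded with a warning.  The
    returned posterior carries split-R-hat diagnostics for every group-level
    parameter; values above ``mcmc.rhat_warn`` raise a warning but never
    abort the fit.
    """
    mcmc = mcmc or McmcSettings()
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    ids, y, t, mask = _prepare_arrays(dataset, biomarker, arm)
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    pats, grps = [], []
    for ss in seeds:
        p, g = _run_chain(y, t, mask, mcmc, np.random.default_rng(ss))
        pats.append(p)
        grps.append(g)
    patient_draws = {
        k: np.stack([p[k] for p in pats]) for k in PATIENT_PARAMS
    }
    group_draws = {k: np.stack([g[k] for g in grps]) for k in GROUP_PARAMS}
    # derived group-level location/spread of the changepoint
    group_draws["mu_t_inflection"] = patient_draws["t_inflection"].mean(axis=2)
    group_draws["sd_t_inflection"] = patient_draws["t_inflection"].std(axis=2, ddof=1)

    diagnostics = {k: _rhat(v) for k, v in group_draws.items()}
    bad = {k: r for k, r in diagnostics.items() if np.isfinite(r) and r > mcmc.rhat_warn}
    if bad:
        warnings.warn(
            f"{biomarker}/{arm}: R-hat above {mcmc.rhat_warn} for "
            f"{sorted(bad)} — treat group summaries with caution", stacklevel=2,
        )
    return HierarchicalPosterior(
        arm=arm, biomarker=biomarker, patient_ids=ids,
        patient_draws=patient_draws, group_draws=group_draws,
        n_chains=mcmc.n_chains, n_draws=mcmc.n_draws, seed=mcmc.seed,
        diagnostics=diagnostics,
    )


def fit_by_arm(dataset: LongitudinalDataset, biomarker: str,
               mcmc: McmcSettings | None = None) -> dict[str, HierarchicalPosterior]:
    """Fit each treatment arm separately (the arms share no parameters)."""
    mcmc = mcmc or McmcSettings()
    out = {}
    for i, arm in enumerate(ARMS):
        arm_mcmc = McmcSettings(**{**mcmc.__dict__, "seed": mcmc.seed + 1000 * i})
        out[arm] = fit_hierarchical(dataset, biomarker, arm_mcmc, arm=arm)
    return out


def save_posterior(posterior: HierarchicalPosterior, path) -> None:
    """Persist draws to a compressed ``.npz`` archive (summaries go to CSV)."""
    payload = {f"patient__{k}": v for k, v in posterior.patient_draws.items()}
    payload.update({f"group__{k}": v for k, v in posterior.group_draws.items()})
    np.savez_compressed(
        path,
        arm=posterior.arm, biomarker=posterior.biomarker,
        patient_ids=np.array(posterior.patient_ids),
        seed=posterior.seed,
        diag_names=np.array(list(posterior.diagnostics)),
        diag_values=np.array(list(posterior.diagnostics.values())),
        **payload,
    )


def load_posterior(path) -> HierarchicalPosterior:
    with np.load(path, allow_pickle=False) as z:
        patient_draws = {
            k.removeprefix("patient__"): z[k] for k in z.files if k.startswith("patient__")
        }
        group_draws = {
            k.removeprefix("group__"): z[k] for k in z.files if k.startswith("group__")
        }
        chains, draws, _ = patient_draws["beta"].shape
        return HierarchicalPosterior(
            arm=str(z["arm"]), biomarker=str(z["biomarker"]),
            patient_ids=[str(p) for p in z["patient_ids"]],
            patient_draws=patient_draws, group_draws=group_draws,
            n_chains=chains, n_draws=draws, seed=int(z["seed"]),
            diagnostics=dict(zip([str(n) for n in z["diag_names"]],
                                 z["diag_values"].astype(float))),
        )


def summarize_posterior(posteriors_by_arm: dict[str, HierarchicalPosterior]):
    """Slope table plus Mann-Whitney arm contrast of patient-level slopes.

    Returns ``(table, comparison)``: the table holds per-arm posterior means
    and intervals of the group-level slopes (per month, log scale); the
    comparison maps ``beta``/``gamma`` to the two-sided Mann-Whitney test of
    the patient-level posterior-mean slopes between arms.
    """
    for arm in ARMS:
        if arm not in posteriors_by_arm:
            raise ValueError(f"missing posterior for arm {arm!r}")
    table = pd.concat(
        [posteriors_by_arm[arm].group_summary() for arm in ARMS], ignore_index=True
    )
    comparison = {}
    for patient_param, group_param in (("beta", "mu_beta"), ("gamma", "mu_gamma")):
        vals = {
            arm: posteriors_by_arm[arm].patient_posterior_means(patient_param).to_numpy()
            for arm in ARMS
        }
        u, p = mann_whitney_u(vals["experimental"], vals["standard"])
        comparison[patient_param] = {
            "U": u, "p": p,
            "experimental_mean": float(
                np.mean(posteriors_by_arm["experimental"].group_draws[group_param])),
            "standard_mean": float(
                np.mean(posteriors_by_arm["standard"].group_draws[group_param])),
        }
    return table, comparison
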