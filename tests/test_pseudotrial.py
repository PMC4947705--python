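import numpy as np
import pytest

import angiotraj as at
from conftest import degenerate_posterior, make_cohort


def _dataset(pfs_days=300.0, n=4):
    """Tiny all-progressed experimental cohort for pseudo-trial runs."""
    import pandas as pd

    ids = [f"p{i}" for i in range(n)]
    rows = []
    for pid in ids:
        rows += [
            (pid, "experimental", "Tie2", -14.0, 100.0, "pretreatment_1", False),
            (pid, "experimental", "Tie2", 0.0, 100.0, "cycle1_end", False),
            (pid, "experimental", "Tie2", pfs_days, 100.0, "progression", True),
        ]
    samples = pd.DataFrame(rows, columns=at.dataset.SAMPLE_COLUMNS)
    patients = pd.DataFrame(
        {"patient_id": ids, "arm": "experimental", "pfs_days": pfs_days,
         "progressed": True}
    )
    return at.LongitudinalDataset(samples, patients)


def rising_params(pfs_days=300.0, rise=0.6, at_pct=0.7):
    """Noiseless trajectory whose rebound reaches ``rise`` over its nadir at
    ``at_pct`` of the progression-free interval."""
    tau_days = pfs_days / 2
    months_to_target = (at_pct * pfs_days - tau_days) / at.DAYS_PER_MONTH
    gamma = np.log(1.0 + rise) / months_to_target
    return at.PiecewiseLinearParams(
        alpha=5.0, beta=-0.3, gamma=gamma,
        t_inflection=tau_days / at.DAYS_PER_MONTH, sigma=0.0,
    )


class TestImputeMonthly:
    def test_monthly_grid_without_jitter(self):
        cfg = at.PseudoTrialConfig(n_replicates=1, visit_jitter_days=0.0)
        p = at.PiecewiseLinearParams(0, 0, 0, 1.0, 0.0)
        s = at.impute_monthly(p, 100.0, cfg)
        assert np.allclose(s.times_days, [30.0, 60.0, 90.0])

    def test_incomplete_month_gives_empty_series(self):
        cfg = at.PseudoTrialConfig(n_replicates=1, visit_jitter_days=0.0)
        p = at.PiecewiseLinearParams(0, 0, 0, 1.0, 0.0)
        assert at.impute_monthly(p, 29.0, cfg).times_days.size == 0

    def test_jitter_stays_within_band_and_ordered(self):
        cfg = at.PseudoTrialConfig(n_replicates=1)
        p = at.PiecewiseLinearParams(0, 0, 0, 1.0, 0.0)
        s = at.impute_monthly(p, 400.0, cfg, seed=3)
        nominal = 30.0 * np.arange(1, s.times_days.size + 1)
        assert np.all(np.abs(s.times_days - nominal) <= 5.0)
        assert np.all(np.diff(s.times_days) > 0)

    def test_noiseless_rising_series_is_monotone_after_inflection(self):
        cfg = at.PseudoTrialConfig(n_replicates=1, visit_jitter_days=0.0)
        p = rising_params()
        s = at.impute_monthly(p, 300.0, cfg)
        after = s.times_days / at.DAYS_PER_MONTH > p.t_inflection
        vals = s.concentrations[after]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            at.PseudoTrialConfig(n_replicates=0)
        with pytest.raises(ValueError):
            at.PseudoTrialConfig(visit_jitter_days=40.0)


class TestSampleDraw:
    def test_degenerate_posterior_returns_that_draw(self):
        p = rising_params()
        post = degenerate_posterior(p, ["p0", "p1"])
        draw = at.sample_pseudo_trajectory(post, "p0", replicate_seed=7)
        assert draw == p

    def test_unknown_patient_rejected(self):
        post = degenerate_posterior(rising_params(), ["p0"])
        with pytest.raises(KeyError):
            at.sample_pseudo_trajectory(post, "ghost", replicate_seed=0)

    def test_monte_carlo_mean_tracks_posterior_mean(self):
        """Empirical mean over many joint draws approaches the posterior
        mean within three Monte-Carlo standard errors."""
        ds = make_cohort(6, 6, seed=17)
        post = at.fit_hierarchical(
            ds, "Tie2", at.McmcSettings(2, 400, 400, seed=1), arm="experimental"
        )
        pid = post.patient_ids[0]
        rng = np.random.default_rng(0)
        draws = np.array([
            at.sample_pseudo_trajectory(post, pid, rng).beta for _ in range(4000)
        ])
        ref = post.patient_draws["beta"][:, :, 0]
        mcse = ref.std() / np.sqrt(4000)
        assert abs(draws.mean() - ref.mean()) < 3 * mcse


class TestRunPseudoTrials:
    def test_deterministic_rising_cohort_predicts_everyone_near_70pct(self):
        ds = _dataset()
        p = rising_params()
        posteriors = {"Tie2": {"experimental": degenerate_posterior(
            p, list(ds.patients["patient_id"]))}}
        cfg = at.PseudoTrialConfig(n_replicates=50, visit_jitter_days=0.0, seed=0)
        res = at.run_pseudo_trials(posteriors, ds, [at.AlarmRule("Tie2", 0.5)], cfg)
        assert res.evaluation.prediction_rate == pytest.approx(100.0)
        assert abs(res.evaluation.mean_prediction_time - 70.0) <= 10.0

    def test_flat_trajectories_never_alarm(self):
        ds = _dataset()
        flat = at.PiecewiseLinearParams(5.0, 0.0, 0.0, 1.0, 0.0)
        posteriors = {"Tie2": {"experimental": degenerate_posterior(
            flat, list(ds.patients["patient_id"]))}}
        cfg = at.PseudoTrialConfig(n_replicates=20, visit_jitter_days=0.0, seed=0)
        res = at.run_pseudo_trials(posteriors, ds, [at.AlarmRule("Tie2", 0.5)], cfg)
        assert res.evaluation.prediction_rate == 0.0

    def test_default_replicate_count_is_5000(self):
        assert at.PseudoTrialConfig().n_replicates == 5000

    def test_missing_posterior_rejected(self):
        ds = _dataset()
        with pytest.raises(KeyError):
            at.run_pseudo_trials({}, ds, [at.AlarmRule("Tie2", 0.5)],
                                 at.PseudoTrialConfig(n_replicates=5))

    def test_or_combination_dominates_components(self):
        ds = make_cohort(8, 8, seed=23)
        fast = at.McmcSettings(2, 300, 300, seed=5)
        posts = {"Tie2": at.fit_by_arm(ds, "Tie2", fast)}
        cfg = at.PseudoTrialConfig(n_replicates=300, seed=2)
        single = at.run_pseudo_trials(posts, ds, [at.AlarmRule("Tie2", 0.5)], cfg)
        strict = at.run_pseudo_trials(posts, ds, [at.AlarmRule("Tie2", 1.2)], cfg)
        both = at.run_pseudo_trials(
            posts, ds, [at.AlarmRule("Tie2", 0.5), at.AlarmRule("Tie2", 1.2)], cfg
        )
        assert both.evaluation.prediction_rate >= max(
            single.evaluation.prediction_rate, strict.evaluation.prediction_rate
        ) - 1.5  # OR of replicate-level alarms; small MC slack across reruns

    def test_seeded_reproducibility(self):
        ds = _dataset()
        p = rising_params()
        posteriors = {"Tie2": {"experimental": degenerate_posterior(
            p, list(ds.patients["patient_id"]))}}
        cfg = at.PseudoTrialConfig(n_replicates=100, seed=9)
        a = at.run_pseudo_trials(posteriors, ds, [at.AlarmRule("Tie2", 0.5)], cfg)
        b = at.run_pseudo_trials(posteriors, ds, [at.AlarmRule("Tie2", 0.5)], cfg)
        assert a.per_patient.equals(b.per_patient)

    def test_mc_error_shrinks_with_replicates(self):
        """Across independent seeds the spread of the per-patient alarm
        probability scales roughly as 1/sqrt(replicates)."""
        ds = _dataset(pfs_days=90.0, n=1)   # three monitoring visits
        noisy = at.PiecewiseLinearParams(5.0, 0.0, 0.0, 1.0, 0.25)
        posteriors = {"Tie2": {"experimental": degenerate_posterior(
            noisy, list(ds.patients["patient_id"]))}}

        def spread(n_rep, seeds):
            probs = []
            for s in seeds:
                cfg = at.PseudoTrialConfig(n_replicates=n_rep, seed=s)
                r = at.run_pseudo_trials(posteriors, ds,
                                         [at.AlarmRule("Tie2", 0.5)], cfg)
                probs.append(r.per_patient["alarm_probability"].iloc[0])
            return np.std(probs)

        s_small = spread(100, range(12))
        s_large = spread(1600, range(12))
        assert s_large < s_small / 2.0   # expect ~1/4, allow factor-2 slack
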