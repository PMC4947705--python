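from itertools import combinations

import numpy as np
import pytest

import angiotraj as at
from conftest import make_cohort


def enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by pairwise-count enumeration."""
    x, y = list(x), list(y)
    pooled = x + y
    n, N = len(x), len(pooled)

    def u_of(subset):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in range(N) if i not in subset]
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    centre = 0.5 * n * (N - n)
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    us = [u_of(s) for s in combinations(range(N), n)]
    p = np.mean([abs(u - centre) >= abs(u_obs - centre) - 1e-12 for u in us])
    return u_obs, float(p)


class TestMannWhitney:
    def test_worked_example_u0_p_third(self):
        u, p = at.mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (3, 6), (5, 5)])
    def test_exact_branch_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.integers(0, 6, size=n1).astype(float)   # coarse grid forces ties
        y = rng.integers(0, 6, size=n2).astype(float)
        u, p = at.mann_whitney_u(x, y)
        u_ref, p_ref = enumeration_oracle(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(0)
        x = rng.integers(0, 10, 30).astype(float)
        y = rng.integers(2, 12, 25).astype(float)
        _, p = at.mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            at.mann_whitney_u([], [1.0])


class TestBonferroni:
    def test_exact_family_division(self):
        assert at.bonferroni_threshold(0.05, 15, 10) == pytest.approx(0.05 / 150)

    def test_rounds_to_printed_cutoff(self):
        """alpha/(15 biomarkers x 10 bins) prints as 0.0003 at one
        significant figure."""
        thr = at.bonferroni_threshold(0.05, 15, 10)
        assert float(f"{thr:.1g}") == 0.0003


class TestNormalizedSeries:
    def test_value_at_baseline_mean_gives_zero_log_ratio(self):
        s = at.to_normalized_series([-14, -1, 30], [4.0, 6.0, 5.0], pfs_days=100)
        assert s.baseline == pytest.approx(5.0)
        assert s.log_ratio[1] == pytest.approx(0.0)

    def test_doubling_gives_log_two(self):
        s = at.to_normalized_series([-14, 50], [10.0, 20.0], pfs_days=100)
        assert s.log_ratio[-1] == pytest.approx(np.log(2), abs=1e-12)

    def test_progression_sample_lands_at_100pct(self):
        s = at.to_normalized_series([-14, 200], [10.0, 12.0], pfs_days=200)
        assert s.pct_pfs[-1] == pytest.approx(100.0)

    def test_baseline_anchor_is_zero_for_everyone(self, small_cohort):
        for s in at.normalize_dataset(small_cohort, "Tie2"):
            assert s.pct_pfs[0] == 0.0
            assert s.log_ratio[0] == 0.0

    def test_single_pretreatment_sample_used_alone(self):
        s = at.to_normalized_series([-1, 40], [8.0, 8.0], pfs_days=80)
        assert s.baseline == pytest.approx(8.0)

    def test_missing_pretreatment_rejected(self):
        with pytest.raises(ValueError):
            at.to_normalized_series([10, 20], [1.0, 2.0], pfs_days=50)


class TestIntervalComparison:
    def test_structure_and_family_threshold(self, small_cohort):
        res = at.interval_arm_comparison(small_cohort, "Tie2")
        assert res.bonferroni == pytest.approx(0.05 / 150)
        assert res.min_p == pytest.approx(res.table["p"].min())
        assert (res.table["bin_high"] - res.table["bin_low"]).eq(10).all()

    def test_distinct_arms_are_detected(self):
        ds = make_cohort(
            20, 20, seed=31,
            slope_before_mean_by_arm={"standard": 0.5, "experimental": -3.4},
            slope_after_mean_by_arm={"standard": 0.5, "experimental": 0.9},
        )
        res = at.interval_arm_comparison(ds, "Tie2")
        assert res.min_p < res.bonferroni

    def test_identical_arms_mostly_null(self):
        """Under identical generative arms the minimum bin p-value rarely
        crosses the family-wise cut-off."""
        hits = 0
        for seed in range(10):
            ds = make_cohort(12, 12, seed=100 + seed)
            res = at.interval_arm_comparison(ds, "Tie2")
            hits += res.min_p < res.bonferroni
        assert hits <= 1


class TestResponseComparison:
    def _labels(self, ds, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        pats = ds.patients["patient_id"].tolist()
        return {p: rng.choice(["CR", "SD", "PR"]) for p in pats}

    def test_pr_patients_never_compared(self, panel_cohort):
        labels = self._labels(panel_cohort)
        table = at.response_comparison(panel_cohort, labels)
        n_cr = sum(v == "CR" for v in labels.values())
        n_sd = sum(v == "SD" for v in labels.values())
        assert (table["n_cr"] <= n_cr).all()
        assert (table["n_sd"] <= n_sd).all()
        assert set(table["biomarker"]) == set(panel_cohort.biomarkers)

    def test_low_baseline_ca125_excluded_from_ca125_row(self, panel_cohort):
        labels = self._labels(panel_cohort)
        # force one CR patient under the detectability limit
        ds2 = panel_cohort
        s = ds2.samples.copy()
        cr = [p for p, l in labels.items() if l == "CR"][0]
        mask = (s["patient_id"] == cr) & (s["biomarker"] == "Ca125") & (s["time_days"] < 0)
        s.loc[mask, "concentration"] = 20.0
        ds_low = at.LongitudinalDataset(s, ds2.patients)
        base = at.response_comparison(ds2, labels).set_index("biomarker")
        low = at.response_comparison(ds_low, labels).set_index("biomarker")
        assert low.loc["Ca125", "n_cr"] == base.loc["Ca125", "n_cr"] - 1
        assert low.loc["Tie2", "n_cr"] == base.loc["Tie2", "n_cr"]

    def test_null_cohort_rarely_significant(self):
        ps = []
        for seed in range(10):
            ds = make_cohort(14, 14, seed=200 + seed)
            labels = self._labels(ds, rng_seed=seed)
            table = at.response_comparison(ds, labels)
            ps.append(float(table["p"].iloc[0]))
        assert np.mean(np.array(ps) > 0.05) >= 0.8

    def test_empty_group_rejected(self, small_cohort):
        labels = {p: "PR" for p in small_cohort.patients["patient_id"]}
        with pytest.raises(ValueError):
            at.response_comparison(small_cohort, labels)
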