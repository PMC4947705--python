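import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import angiotraj as at
from angiotraj.rules import nadir_alarm_batch


def series(values, times=None, pfs=None, progressed=True):
    values = np.asarray(values, dtype=float)
    times = np.asarray(times if times is not None else
                       30.0 * np.arange(1, values.size + 1), dtype=float)
    return at.MonitoredSeries(times, values, float(pfs or times[-1]), progressed)


def oracle_alarm(values, times, threshold):
    """Brute force: re-derive the prefix minimum and test every step."""
    for k in range(len(values)):
        nadir = min(values[: k + 1])
        if values[k] >= nadir * (1.0 + threshold):
            return times[k]
    return None


class TestNadirAlarm:
    def test_alarm_after_rebound(self):
        s = series([100, 80, 60, 70, 95])
        assert at.nadir_alarm(s, at.AlarmRule("b", 0.5)) == 150.0   # month 5

    def test_lower_threshold_alarms_earlier(self):
        s = series([100, 80, 60, 70, 95])
        assert at.nadir_alarm(s, at.AlarmRule("b", 0.1)) == 120.0   # month 4

    def test_strictly_decreasing_never_alarms(self):
        s = series([100, 90, 80, 70])
        assert at.nadir_alarm(s, at.AlarmRule("b", 0.5)) is None

    def test_exact_threshold_boundary_triggers(self):
        s = series([100, 60, 90])
        assert at.nadir_alarm(s, at.AlarmRule("b", 0.5)) == 90.0

    def test_confirmation_requires_second_exceedance(self):
        s = series([100, 60, 95, 70, 99, 99])
        rule = at.AlarmRule("b", 0.5, require_confirmation=True)
        assert at.nadir_alarm(s, rule) == 180.0   # 99, 99 are consecutive hits

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError):
            at.AlarmRule("b", 0.0)

    @given(st.lists(st.sampled_from(range(10, 101, 10)), min_size=1, max_size=8),
           st.sampled_from([0.1, 0.25, 0.5, 1.0]))
    def test_matches_bruteforce_oracle(self, values, threshold):
        s = series(values)
        expected = oracle_alarm(values, s.times_days, threshold)
        assert at.nadir_alarm(s, at.AlarmRule("b", threshold)) == expected

    @given(st.lists(st.floats(1.0, 100.0), min_size=2, max_size=10),
           st.floats(0.05, 1.5))
    def test_appending_never_changes_triggered_alarm(self, values, threshold):
        """Online consistency: a fired alarm is immutable under new data."""
        rule = at.AlarmRule("b", threshold)
        full = series(values)
        fired = at.nadir_alarm(full, rule)
        extended = series(values + [1.0])
        if fired is not None:
            assert at.nadir_alarm(extended, rule) == fired

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        conc = np.exp(rng.normal(0, 0.5, size=(200, 7)))
        times = 30.0 * np.arange(1, 8)
        batch = nadir_alarm_batch(conc, times, 0.5)
        for i in range(200):
            scalar = at.nadir_alarm(series(conc[i]), at.AlarmRule("b", 0.5))
            if np.isnan(batch[i]):
                assert scalar is None
            else:
                assert scalar == batch[i]


class TestGcigAlarm:
    def test_doubling_from_nadir_alarms(self):
        assert at.gcig_ca125_alarm(series([50, 20, 45])) == 90.0

    def test_below_doubling_stays_silent(self):
        assert at.gcig_ca125_alarm(series([50, 30, 55])) is None

    def test_single_point_cannot_alarm(self):
        assert at.gcig_ca125_alarm(series([50])) is None

    def test_equivalent_to_threshold_one(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            vals = np.exp(rng.normal(3, 0.8, size=6))
            s = series(vals)
            assert at.gcig_ca125_alarm(s) == at.nadir_alarm(s, at.AlarmRule("Ca125", 1.0))


class TestCombinedOr:
    @pytest.mark.parametrize(
        "components, expected",
        [((180.0, 120.0), 120.0), ((None, 120.0), 120.0), ((None, None), None)],
    )
    def test_earliest_component_wins(self, components, expected):
        assert at.combined_or_alarm(components) == expected

    def test_empty_components_rejected(self):
        with pytest.raises(ValueError):
            at.combined_or_alarm([])


class TestCohortEvaluation:
    def test_rate_and_mean_time(self):
        alarms = {"p1": 100.0, "p2": 120.0, "p3": None}
        pfs = {"p1": 200.0, "p2": 200.0, "p3": 200.0}
        ev = at.evaluate_rule_over_cohort(alarms, pfs)
        assert ev.prediction_rate == pytest.approx(100 * 2 / 3)
        assert ev.mean_prediction_time == pytest.approx(55.0)
        assert ev.n_progressed == 3

    def test_alarms_after_progression_do_not_count(self):
        ev = at.evaluate_rule_over_cohort(
            {"p1": 300.0, "p2": 400.0}, {"p1": 200.0, "p2": 200.0}
        )
        assert ev.prediction_rate == 0.0

    def test_censored_patients_excluded_from_denominator(self):
        ev = at.evaluate_rule_over_cohort(
            {"p1": 100.0, "p2": 100.0}, {"p1": 200.0, "p2": 200.0},
            progressed={"p1": True, "p2": False},
        )
        assert ev.n_progressed == 1
        assert ev.prediction_rate == 100.0

    def test_no_progressed_patients_rejected(self):
        with pytest.raises(ValueError):
            at.evaluate_rule_over_cohort({"p": 10.0}, {"p": 50.0}, {"p": False})


class TestThresholdSweep:
    def _cohort(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        out = {}
        for i in range(n):
            vals = np.exp(rng.normal(4, 0.6, size=8))
            out[f"p{i}"] = series(vals)
        return out

    def test_rate_nonincreasing_in_threshold(self):
        cohort = self._cohort()
        evals = at.threshold_sweep(cohort, [0.1, 0.3, 0.5, 0.8, 1.2])
        rates = [e.prediction_rate for e in evals]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_alarm_time_nondecreasing_in_threshold(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            vals = np.exp(rng.normal(0, 0.7, size=8))
            s = series(vals)
            prev = -np.inf
            for thr in (0.1, 0.3, 0.6, 1.0):
                a = at.nadir_alarm(s, at.AlarmRule("b", thr))
                cur = np.inf if a is None else a
                assert cur >= prev
                prev = cur

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            at.threshold_sweep(self._cohort(), [])

    def test_step_cohort_sharp_cutoff(self):
        """Noiseless series rising exactly 60% over nadir predict everyone
        at thresholds up to 0.6 and no one above."""
        cohort = {
            f"p{i}": series([100.0, 50.0, 80.0]) for i in range(5)
        }
        evals = at.threshold_sweep(cohort, [0.3, 0.6, 0.61, 1.0])
        assert [e.prediction_rate for e in evals] == [100.0, 100.0, 0.0, 0.0]

    def test_or_rate_dominates_components(self):
        a = self._cohort(seed=1)
        b = self._cohort(seed=2)
        rule = at.AlarmRule("x", 0.5)
        alarms_a = {p: at.nadir_alarm(s, rule) for p, s in a.items()}
        alarms_b = {p: at.nadir_alarm(s, rule) for p, s in b.items()}
        combined = {p: at.combined_or_alarm([alarms_a[p], alarms_b[p]]) for p in a}
        pfs = {p: s.pfs_days for p, s in a.items()}
        rate = lambda al: at.evaluate_rule_over_cohort(al, pfs).prediction_rate
        assert rate(combined) >= max(rate(alarms_a), rate(alarms_b))
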