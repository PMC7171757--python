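"""Survival metrics: concordance, time-dependent AUC, KM, log-rank,
optimal cutpoint and proportional-hazards tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score
from sksurv.metrics import concordance_index_censored

from radsurv.evaluation import (cox_table, evaluate_endpoint, harrell_cindex,
                                km_estimate, logrank_test, optimal_cutpoint,
                                time_dependent_auc)


class TestHarrellCindex:
    def test_perfect_reverse_ordering(self):
        t = np.arange(1.0, 51.0)
        assert harrell_cindex(-t, t, np.ones(50, dtype=int)) == 1.0

    def test_three_patient_enumeration(self):
        t = np.array([2.0, 4.0, 6.0])
        e = np.ones(3, dtype=int)
        assert harrell_cindex([0.9, 0.8, 0.1], t, e) == 1.0
        assert harrell_cindex([0.1, 0.8, 0.9], t, e) == 0.0

    def test_all_tied_risks_give_half(self):
        t = np.arange(1.0, 11.0)
        assert harrell_cindex(np.zeros(10), t, np.ones(10, dtype=int)) == 0.5

    def test_censored_short_times_not_comparable(self):
        # first patient censored at t=1: no pair has an observed shorter time
        c = harrell_cindex([1.0, 0.0], [1.0, 2.0], [0, 1])
        assert np.isnan(c)

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 80
            risk = rng.normal(0, 1, n)
            time = rng.exponential(10, n) + 0.01  # continuous: no time ties
            event = rng.random(n) < 0.7
            ours = harrell_cindex(risk, time, event.astype(int))
            ref = concordance_index_censored(event, time, risk)[0]
            assert ours == pytest.approx(ref, abs=1e-12)

    @given(st.integers(0, 10**6))
    def test_antisymmetry_under_risk_negation(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        risk = rng.normal(0, 1, n)  # continuous: ties have probability 0
        time = rng.exponential(5, n) + 0.01
        event = (rng.random(n) < 0.8).astype(int)
        c = harrell_cindex(risk, time, event)
        if not np.isnan(c):
            assert harrell_cindex(-risk, time, event) == pytest.approx(1.0 - c)


class TestTimeDependentAuc:
    def test_perfect_separation_without_censoring(self):
        t = np.array([10.0, 20.0, 30.0, 50.0, 60.0, 70.0])
        e = np.ones(6, dtype=int)
        assert time_dependent_auc(-t, t, e, t=36.0) == pytest.approx(1.0)

    def test_equals_binary_auc_without_censoring(self):
        rng = np.random.default_rng(1)
        n = 200
        time = rng.exponential(40, n) + 0.01
        event = np.ones(n, dtype=int)
        risk = -np.log(time) + rng.normal(0, 0.5, n)
        auc = time_dependent_auc(risk, time, event, t=36.0)
        binary = roc_auc_score(time <= 36.0, risk)
        assert auc == pytest.approx(binary, abs=1e-10)

    def test_undefined_without_cases(self):
        t = np.full(20, 100.0)
        with pytest.warns(UserWarning):
            assert np.isnan(time_dependent_auc(np.arange(20.0), t,
                                               np.ones(20, int), t=36.0))


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        km = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert km.survival_at(2.5) == pytest.approx(0.5)
        assert km.survival_at(0.5) == pytest.approx(1.0)

    def test_no_events_flat_at_one(self):
        km = km_estimate([5.0, 10.0, 15.0], [0, 0, 0])
        assert km.survival_at(14.0) == pytest.approx(1.0)

    def test_flat_after_last_event_with_trailing_censoring(self):
        km = km_estimate([2.0, 4.0, 6.0, 8.0], [1, 1, 0, 0])
        assert km.survival_at(5.0) == km.survival_at(8.0) == pytest.approx(0.5)


def manual_logrank(time_a, event_a, time_b, event_b):
    """Textbook O-E log-rank chi-square, computed per distinct event time."""
    times = np.concatenate([time_a, time_b])
    events = np.concatenate([event_a, event_b])
    group = np.concatenate([np.zeros(len(time_a)), np.ones(len(time_b))])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 1, 0])
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_manual_computation(self):
        ta, ea = np.array([2.0, 5.0, 9.0]), np.array([1, 1, 1])
        tb, eb = np.array([3.0, 7.0, 11.0]), np.array([1, 1, 0])
        stat, _ = logrank_test(ta, ea, tb, eb)
        assert stat == pytest.approx(manual_logrank(ta, ea, tb, eb), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [1])


class TestOptimalCutpoint:
    def test_cutoff_separates_two_risk_clusters(self):
        rng = np.random.default_rng(2)
        n = 40
        risk = np.concatenate([rng.normal(0, 0.1, n), rng.normal(5, 0.1, n)])
        time = np.concatenate([rng.exponential(100, n), rng.exponential(5, n)]) + 0.01
        event = np.ones(2 * n, dtype=int)
        cut = optimal_cutpoint(risk, time, event)
        assert 1.0 < cut < 5.0
        assert (risk < cut).sum() == n  # low cluster entirely below the cutoff

    def test_scan_equals_brute_force_maximum(self):
        rng = np.random.default_rng(3)
        n = 40
        risk = rng.normal(0, 1, n)
        time = rng.exponential(20, n) * np.exp(-0.5 * risk) + 0.01
        event = (rng.random(n) < 0.8).astype(int)
        cut = optimal_cutpoint(risk, time, event)
        min_count = int(np.ceil(0.1 * n))
        best_stat, best_c = -np.inf, None
        for c in np.unique(risk):
            lo = risk < c
            if lo.sum() < min_count or (~lo).sum() < min_count:
                continue
            stat, _ = logrank_test(time[lo], event[lo], time[~lo], event[~lo])
            if stat > best_stat:
                best_stat, best_c = stat, c
        assert cut == pytest.approx(best_c)

    def test_identical_risks_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutpoint(np.ones(20), np.arange(1.0, 21.0), np.ones(20, int))


class TestCoxTable:
    def test_recovers_known_hazard_ratio(self):
        """Binary covariate with true HR=2 under exponential hazards."""
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.integers(0, 2, n)
        time = rng.exponential(1.0, n) / np.exp(np.log(2.0) * x)
        cov = pd.DataFrame({"x": x})
        table = cox_table(cov, time, np.ones(n, dtype=int))
        assert 1.8 <= table.loc["x", "hr"] <= 2.2

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(5)
        covered = 0
        n_reps = 100
        for _ in range(n_reps):
            n = 100
            x = rng.normal(0, 1, n)
            time = rng.exponential(10, n)
            tab = cox_table(pd.DataFrame({"x": x}), time, np.ones(n, dtype=int))
            covered += tab.loc["x", "ci_low"] <= 1.0 <= tab.loc["x", "ci_high"]
        assert 0.88 <= covered / n_reps <= 0.99

    def test_duplicated_covariate_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 50)
        cov = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="collinear"):
            cox_table(cov, rng.exponential(5, 50), np.ones(50, dtype=int))

    def test_separation_flagged_unstable(self):
        """All events in one level of a binary covariate: monotone
        likelihood is reported as unstable, not as a number."""
        n = 40
        x = np.repeat([0, 1], n // 2)
        time = np.linspace(1, 40, n)
        event = x.copy()  # events only in group 1
        tab = cox_table(pd.DataFrame({"x": x}), time, event)
        assert bool(tab.loc["x", "unstable"])
        assert np.isnan(tab.loc["x", "hr"])


def test_endpoint_report_structure():
    rng = np.random.default_rng(7)
    n = 80
    risk = rng.normal(0, 1, n)
    time = rng.exponential(40, n) * np.exp(-0.8 * risk) + 0.01
    event = (rng.random(n) < 0.8).astype(int)
    rep = evaluate_endpoint(risk[:50], time[:50], event[:50],
                            risk[50:], time[50:], event[50:])
    assert 0 <= rep["cindex_validation"] <= 1
    assert rep["n_low_risk"] + rep["n_high_risk"] == 30
    assert 0 <= rep["logrank_p"] <= 1
    assert 0 <= rep["survival_low_pct"] <= 100
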