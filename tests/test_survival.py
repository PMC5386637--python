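"""Survival primitives: median splits, Kaplan-Meier, log-rank, Cox."""

import numpy as np
import pandas as pd
import pytest

from survscreen import ConvergenceError, ValidationError
from survscreen.survival import (
    cox_fit,
    dichotomize_by_median,
    encode_clinical,
    km_estimate,
    logrank_many,
    logrank_test,
)

from conftest import random_survival


def brute_force_km(time, event):
    """Product-limit estimator by explicit looping over event times."""
    times = sorted(set(t for t, e in zip(time, event) if e == 1))
    s, out = 1.0, []
    for tj in times:
        n_risk = sum(1 for t in time if t >= tj)
        d = sum(1 for t, e in zip(time, event) if t == tj and e == 1)
        s *= 1.0 - d / n_risk
        out.append((tj, s))
    return out


def brute_force_logrank(ta, ea, tb, eb):
    """Direct O/E/V tabulation over distinct event times."""
    times = sorted(set(list(ta[ea == 1]) + list(tb[eb == 1])))
    O = E = V = 0.0
    for tj in times:
        n1 = float((ta >= tj).sum())
        n2 = float((tb >= tj).sum())
        d1 = float(((ta == tj) & (ea == 1)).sum())
        d2 = float(((tb == tj) & (eb == 1)).sum())
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V if V > 0 else 0.0


class TestDichotomize:
    def test_balanced_even_split(self):
        high, degen = dichotomize_by_median([1, 2, 3, 4])
        assert list(high) == [False, False, True, True]
        assert not degen

    def test_ties_at_median_go_low(self):
        high, degen = dichotomize_by_median([0, 0, 0, 5])
        assert list(high) == [False, False, False, True]
        assert not degen

    def test_all_equal_is_degenerate(self):
        _, degen = dichotomize_by_median([0, 0, 0, 0])
        assert degen

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            dichotomize_by_median([1.0])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # deaths at 1 and 3, censored at 2: S(1)=2/3, S(3)=0
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert np.allclose(km.event_times, [1, 3])
        assert np.allclose(km.survival, [2 / 3, 0.0])

    def test_all_censored_survival_is_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.event_times.size == 0
        assert np.allclose(km.survival_at([0.5, 10.0]), 1.0)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 25))
            time, event = random_survival(rng, n)
            km = km_estimate(time, event)
            expected = brute_force_km(time, event)
            assert len(expected) == km.event_times.size
            for (tj, sj), t_obs, s_obs in zip(expected, km.event_times, km.survival):
                assert tj == t_obs
                assert abs(sj - s_obs) < 1e-10

    def test_left_limit_evaluation(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert km.survival_at([2], side="left")[0] == 0.75
        assert km.survival_at([2], side="right")[0] == 0.5


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.array([1, 0, 1, 1, 0])
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_in_group_order(self, rng):
        ta, ea = random_survival(rng, 30)
        tb, eb = random_survival(rng, 25)
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_observed_equals_expected_total(self, rng):
        ta, ea = random_survival(rng, 40)
        tb, eb = random_survival(rng, 35)
        res = logrank_test(ta, ea, tb, eb)
        assert sum(res.observed) == pytest.approx(sum(res.expected), abs=1e-9)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            na, nb = (int(x) for x in rng.integers(4, 30, 2))
            ta, ea = random_survival(rng, na)
            tb, eb = random_survival(rng, nb)
            res = logrank_test(ta, ea, tb, eb)
            assert res.statistic == pytest.approx(brute_force_logrank(ta, ea, tb, eb), abs=1e-10)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        ta, ea = random_survival(rng, 60)
        tb, eb = random_survival(rng, 50)
        res = logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-10)

    def test_no_events_gives_p_one(self):
        res = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_vectorised_agrees_with_scalar(self, rng):
        n = 50
        time, event = random_survival(rng, n)
        high = rng.random((20, n)) < 0.5
        stat, p, degen = logrank_many(high, time, event)
        for f in range(20):
            if degen[f]:
                continue
            ref = logrank_test(time[high[f]], event[high[f]], time[~high[f]], event[~high[f]])
            assert stat[f] == pytest.approx(ref.statistic, abs=1e-10)

    def test_null_rejection_rate_calibrated(self):
        # two groups drawn from one distribution: rejection at 0.05 ~ 0.05
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            t = rng.exponential(100, 200) + 0.1
            e = (rng.random(200) > 0.3).astype(int)
            g = np.zeros(200, bool)
            g[:100] = True
            stat, p, _ = logrank_many(g[None, :], t, e)
            rejections += p[0] < 0.05
        assert 0.035 <= rejections / reps <= 0.065


class TestCox:
    def test_planted_binary_effect_recovered(self):
        rng = np.random.default_rng(5)
        n = 800
        x = (rng.random(n) < 0.5).astype(float)
        beta = np.log(3.5)
        t = rng.exponential(1.0, n) / (1e-3 * np.exp(beta * x))
        fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(n))
        row = fit.summary.loc["x"]
        assert abs(row["coef"] - beta) < 3 * row["se"]
        assert row["ci95_low"] <= row["hazard_ratio"] <= row["ci95_high"]

    def test_loglik_improves_over_null(self):
        rng = np.random.default_rng(6)
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n) / np.exp(0.8 * x)
        fit = cox_fit(pd.DataFrame({"x": x}), t + 1e-6, np.ones(n))
        assert fit.log_likelihood >= fit.log_likelihood_null

    def test_matches_exponential_rate_ratio(self):
        # single binary covariate, exponential data, no censoring: Cox beta
        # approaches the closed-form log rate ratio log((d1/T1)/(d0/T0))
        rng = np.random.default_rng(7)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0, n) / np.exp(1.0 * x)
        fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(n))
        d1, d0 = x.sum(), n - x.sum()
        rate_ratio = (d1 / t[x == 1].sum()) / (d0 / t[x == 0].sum())
        assert fit.summary.loc["x", "coef"] == pytest.approx(np.log(rate_ratio), abs=0.1)

    def test_constant_column_rejected(self):
        with pytest.raises(ValidationError):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), [1, 2, 3], [1, 1, 1])

    def test_separation_fails_loudly(self):
        # perfect separation: covariate order identical to death order
        t = np.arange(1.0, 41.0)
        x = np.arange(40.0)
        with pytest.raises(ConvergenceError):
            cox_fit(pd.DataFrame({"x": x}), t, np.ones(40))


class TestEncodeClinical:
    def test_reference_coding(self):
        clin = pd.DataFrame(
            {
                "stage": ["I", "II", "III", "IV"],
                "grade": [1, 2, 3, 4],
                "age": [50.0, 60.0, 70.0, 80.0],
                "sex": ["M", "F", "M", "F"],
            }
        )
        d = encode_clinical(clin, marker_high=[0, 1, 0, 1])
        assert d.loc[0].tolist() == [0, 0, 0, 0, 0, 50.0, 1, 0]
        assert d.loc[3, "stage_IV"] == 1 and d.loc[3, "grade_4"] == 1

    def test_bad_stage_rejected(self):
        clin = pd.DataFrame({"stage": ["V"], "grade": [2], "age": [60.0], "sex": ["M"]})
        with pytest.raises(ValidationError):
            encode_clinical(clin)
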