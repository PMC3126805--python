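"""Kaplan-Meier, Cox partial likelihood and time-dependent ROC."""

import math

import numpy as np
import pandas as pd
import pytest

from mirprog.survival import (SurvivalOutcome, censor_at, compare_markers, cox_fit,
                              kaplan_meier, km_survival_at, td_roc)
from mirprog.synthetic import generate_survival_cohort


def outcomes(times, events):
    return [SurvivalOutcome(f"s{i}", t, e) for i, (t, e) in enumerate(zip(times, events))]


class TestCensorAt:
    def test_event_after_horizon_censored(self):
        out = censor_at(outcomes([12.0], [True]), 10.0)
        assert (out[0].time, out[0].event) == (10.0, False)

    def test_event_before_horizon_unchanged(self):
        out = censor_at(outcomes([9.9], [True]), 10.0)
        assert (out[0].time, out[0].event) == (9.9, True)

    def test_censored_early_unchanged(self):
        out = censor_at(outcomes([3.0], [False]), 10.0)
        assert (out[0].time, out[0].event) == (3.0, False)


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curves = kaplan_meier(outcomes([1.0, 2.0, 3.0], [False] * 3))
        assert (curves["all"]["survival"] == 1.0).all()

    def test_single_event_quarter_drop(self):
        curves = kaplan_meier(outcomes([1.0, 2.0, 3.0, 4.0], [True, False, False, False]))
        c = curves["all"].set_index("time")["survival"]
        assert c.loc[1.0] == pytest.approx(0.75)

    def test_hand_product_limit_toy(self):
        # times 1,2,3,4 with events 1,1,0,1: S = 3/4, 1/2, 1/2, 0
        curves = kaplan_meier(outcomes([1.0, 2.0, 3.0, 4.0], [True, True, False, True]))
        c = curves["all"].set_index("time")["survival"]
        assert c.loc[1.0] == pytest.approx(0.75)
        assert c.loc[2.0] == pytest.approx(0.5)
        assert c.loc[4.0] == pytest.approx(0.0)

    def test_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(5.0, size=40)
        curves = kaplan_meier(outcomes(times, [True] * 40))
        c = curves["all"]
        for t, s in zip(c["time"], c["survival"]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_km_survival_at_matches_full_curve(self, rng):
        times = rng.exponential(5.0, size=60)
        events = rng.random(60) < 0.7
        c = kaplan_meier(outcomes(times, events))["all"].set_index("time")["survival"]
        for t in (1.0, 3.0, 8.0):
            expected = c[c.index <= t].iloc[-1] if (c.index <= t).any() else 1.0
            assert km_survival_at(times, events, t) == pytest.approx(expected)


def partial_likelihood(beta, times, events, x):
    """Brute-force log partial likelihood (no ties)."""
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxFit:
    def test_matches_grid_search_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.array([True, True, True, False, True])
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        cov = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(5)])
        fit = cox_fit(cov, outcomes(times, events))
        grid = np.linspace(-4, 4, 8001)
        ll = [partial_likelihood(b, times, events, x) for b in grid]
        beta_oracle = grid[int(np.argmax(ll))]
        assert fit.coefficients.iloc[0] == pytest.approx(beta_oracle, abs=2e-3)

    def test_null_covariate_near_zero_large_n(self):
        group, out = generate_survival_cohort(1500, 0.5, 0.08, 0.0, 0.05, 20.0, seed=5)
        cov = pd.DataFrame({"g": group.astype(float)}, index=[o.sample_id for o in out])
        fit = cox_fit(cov, out)
        assert abs(fit.coefficients.iloc[0]) < 0.15
        assert fit.ci_95["lower"].iloc[0] < 1.0 < fit.ci_95["upper"].iloc[0]

    def test_duplicated_subjects_leave_beta_unchanged(self):
        group, out = generate_survival_cohort(120, 0.5, 0.1, 0.8, 0.05, 20.0, seed=3)
        cov = pd.DataFrame({"g": group.astype(float)}, index=[o.sample_id for o in out])
        fit1 = cox_fit(cov, out)
        out2 = out + [SurvivalOutcome(o.sample_id + "_dup", o.time, o.event) for o in out]
        cov2 = pd.DataFrame({"g": np.tile(group.astype(float), 2)},
                            index=[o.sample_id for o in out2])
        fit2 = cox_fit(cov2, out2)
        # duplication creates ties; Efron's tie correction perturbs the
        # partial likelihood by O(1/n), so equality is approximate
        assert fit2.coefficients.iloc[0] == pytest.approx(fit1.coefficients.iloc[0], abs=0.02)

    def test_constant_covariate_rejected(self):
        out = outcomes([1.0, 2.0, 3.0], [True, True, False])
        cov = pd.DataFrame({"c": [1.0, 1.0, 1.0]}, index=[o.sample_id for o in out])
        with pytest.raises(ValueError, match="constant"):
            cox_fit(cov, out)

    def test_no_events_rejected(self):
        out = outcomes([1.0, 2.0], [False, False])
        cov = pd.DataFrame({"x": [0.0, 1.0]}, index=[o.sample_id for o in out])
        with pytest.raises(ValueError, match="events"):
            cox_fit(cov, out)

    def test_hazard_ratios_are_exp_coefficients(self):
        group, out = generate_survival_cohort(200, 0.4, 0.1, 1.0, 0.05, 20.0, seed=8)
        cov = pd.DataFrame({"g": group.astype(float)}, index=[o.sample_id for o in out])
        fit = cox_fit(cov, out)
        assert fit.hazard_ratios.iloc[0] == pytest.approx(
            math.exp(fit.coefficients.iloc[0]))


def auc_pairwise_oracle(marker, times, horizon):
    """Concordance between marker and event-by-horizon status (no censoring)."""
    case = times <= horizon
    num = ties = 0
    for i in np.flatnonzero(case):
        for j in np.flatnonzero(~case):
            num += marker[i] > marker[j]
            ties += marker[i] == marker[j]
    return (num + 0.5 * ties) / (case.sum() * (~case).sum())


class TestTdRoc:
    def test_perfect_marker_auc_one(self, rng):
        times = rng.exponential(5.0, size=50)
        res = td_roc(-times, outcomes(times, [True] * 50), horizon=5.0)
        assert res.auc == pytest.approx(1.0)

    def test_independent_marker_auc_near_half(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            _, out = generate_survival_cohort(200, 0.5, 0.08, 0.0, 0.05, 20.0, seed=100 + seed)
            aucs.append(td_roc(rng.normal(size=200), out, 10.0).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_matches_pairwise_oracle_without_censoring(self, rng):
        times = rng.exponential(6.0, size=30)
        marker = rng.normal(size=30) + 0.3 * (times < 6.0)
        res = td_roc(marker, outcomes(times, [True] * 30), horizon=6.0)
        assert res.auc == pytest.approx(auc_pairwise_oracle(marker, times, 6.0), abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        _, out = generate_survival_cohort(100, 0.5, 0.1, 1.0, 0.05, 20.0, seed=17)
        marker = rng.normal(size=100)
        a = td_roc(marker, out, 10.0).auc
        b = td_roc(np.exp(marker), out, 10.0).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_bounds_and_monotone_curve(self, rng):
        _, out = generate_survival_cohort(150, 0.5, 0.1, 0.7, 0.08, 20.0, seed=23)
        res = td_roc(rng.normal(size=150), out, 10.0)
        assert np.all((res.sensitivity >= 0) & (res.sensitivity <= 1))
        assert np.all((res.specificity >= 0) & (res.specificity <= 1))

    def test_no_events_before_horizon_rejected(self):
        with pytest.raises(ValueError, match="events"):
            td_roc(np.array([1.0, 2.0]), outcomes([5.0, 6.0], [True, True]), horizon=1.0)


class TestCompareMarkers:
    def test_marker_vs_itself_null(self):
        group, out = generate_survival_cohort(80, 0.5, 0.1, 1.0, 0.05, 20.0, seed=31)
        rng = np.random.default_rng(31)
        m = group + rng.normal(0, 0.5, size=80)
        table = compare_markers({"a": m, "b": m.copy()}, out, 10.0, n_boot=100, seed=1)
        assert table["mean_diff_loghr"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert table["p_loghr"].iloc[0] == pytest.approx(1.0)

    def test_strong_vs_null_marker_significant(self):
        group, out = generate_survival_cohort(120, 0.5, 0.06, 1.8, 0.05, 20.0, seed=41)
        rng = np.random.default_rng(41)
        strong = group + rng.normal(0, 0.3, size=120)
        null = rng.normal(size=120)
        table = compare_markers({"strong": strong, "null": null}, out, 10.0,
                                n_boot=100, seed=2)
        assert table["mean_diff_loghr"].iloc[0] > 0
        assert table["p_loghr"].iloc[0] < 0.01
        assert table["p_auc"].iloc[0] < 0.05
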