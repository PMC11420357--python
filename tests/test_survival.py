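"""Endpoints, Kaplan-Meier, ARR, log-rank, and Cox recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from phenomap import synth
from phenomap.survival import (
    ALL_CAUSE_DEATH,
    COMPOSITE,
    apply_endpoint,
    arr_table,
    cox_fit,
    km_estimate,
    logrank,
    reverse_km,
)


def records_frame(rows):
    return pd.DataFrame(
        rows, columns=["time_years", "event", "censor_reason", "device"]
    )


class TestApplyEndpoint:
    def test_death_event_under_both(self):
        rec = records_frame([[3.0, 1, "none", "CRT-P"]])
        for spec in (ALL_CAUSE_DEATH, COMPOSITE):
            t, e = apply_endpoint(rec, spec)
            assert t[0] == 3.0 and e[0]

    def test_htx_censors_primary_counts_composite(self):
        rec = records_frame([[2.0, 0, "htx", "CRT-P"]])
        _, e1 = apply_endpoint(rec, ALL_CAUSE_DEATH)
        _, e2 = apply_endpoint(rec, COMPOSITE)
        assert not e1[0] and e2[0]

    def test_admin_censored_under_both(self):
        rec = records_frame([[10.0, 0, "admin", "CRT-D"]])
        for spec in (ALL_CAUSE_DEATH, COMPOSITE):
            _, e = apply_endpoint(rec, spec)
            assert not e[0]

    def test_unknown_reason_errors(self):
        rec = records_frame([[1.0, 0, "typo", "CRT-P"]])
        with pytest.raises(ValueError):
            apply_endpoint(rec, ALL_CAUSE_DEATH)

    def test_composite_event_count_at_least_primary(self, small_cohort):
        _, _, records, _ = small_cohort
        _, e1 = apply_endpoint(records, ALL_CAUSE_DEATH)
        _, e2 = apply_endpoint(records, COMPOSITE)
        assert e2.sum() >= e1.sum()


class TestKaplanMeier:
    def test_hand_example(self):
        curve = km_estimate([1.0, 2.0, 3.0], [True, True, False])
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(2.0) == pytest.approx(1 / 3)
        assert curve.survival_at(3.0) == pytest.approx(1 / 3)
        assert curve.survival_at(0.5) == 1.0

    def test_no_events(self):
        curve = km_estimate([1.0, 2.0], [False, False])
        assert curve.survival_at(2.0) == 1.0
        assert curve.variance_at(2.0) == 0.0

    def test_monotone_and_ci_order(self, rng):
        t = rng.exponential(5.0, 300)
        e = rng.random(300) < 0.7
        curve = km_estimate(t, e)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert (curve.ci_lo <= curve.survival + 1e-12).all()
        assert (curve.survival <= curve.ci_hi + 1e-12).all()

    def test_consistency_against_exponential(self):
        lam = 0.25
        rng = np.random.default_rng(99)
        t = rng.exponential(1 / lam, 5000)
        curve = km_estimate(t, np.ones(5000, bool))
        assert abs(curve.survival_at(1 / lam) - math.exp(-1)) < 0.02

    def test_matches_lifelines_survival(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(3.0, 200)
        e = rng.random(200) < 0.6
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for x in (1.0, 2.0, 5.0):
            assert curve.survival_at(x) == pytest.approx(
                float(kmf.survival_function_at_times(x).iloc[0])
            )


class TestReverseKM:
    def test_all_admin_censored(self):
        med, (q1, q3) = reverse_km([8.0] * 20, [False] * 20)
        assert med == 8.0

    def test_all_deaths_median_undefined(self):
        with pytest.warns(UserWarning):
            med, _ = reverse_km([1.0, 2.0, 3.0], [True, True, True])
        assert math.isnan(med)

    def test_admin_censor_year_recovered(self):
        cfg = synth.two_arm_config(2000, 1.0, baseline_hazard=0.05,
                                   admin_censor_years=9.0, seed=21)
        _, records, _ = synth.generate_cohort(cfg)
        t, e = apply_endpoint(records)
        med, _ = reverse_km(t, e)
        assert med == pytest.approx(9.0, abs=0.26)


class TestARR:
    def test_identical_curves_zero_not_significant(self, rng):
        t = rng.exponential(4.0, 400)
        e = rng.random(400) < 0.8
        c = km_estimate(t, e)
        entries = arr_table(c, c, [1, 2, 3])
        for ent in entries:
            assert ent.arr == pytest.approx(0.0)
            assert not ent.significant

    def test_known_difference_significant(self):
        # tiny variances from large n, 5pp mortality gap at the horizon
        rng = np.random.default_rng(17)
        tA = rng.exponential(1 / 0.131, 20000)  # S(5) ~ 0.52
        tB = rng.exponential(1 / 0.112, 20000)  # S(5) ~ 0.57
        cA = km_estimate(np.minimum(tA, 8.0), tA <= 8.0)
        cB = km_estimate(np.minimum(tB, 8.0), tB <= 8.0)
        (ent,) = arr_table(cA, cB, [5.0])
        assert ent.arr == pytest.approx(5.0, abs=1.8)
        assert ent.significant

    def test_horizon_beyond_support_flagged(self):
        c = km_estimate([1.0, 2.0], [True, True])
        (ent,) = arr_table(c, c, [50.0])
        assert not ent.available

    def test_significance_flag_matches_ci(self, small_cohort):
        _, _, records, _ = small_cohort
        t, e = apply_endpoint(records)
        crtd = (records["device"] == "CRT-D").to_numpy()
        cP = km_estimate(t[~crtd], e[~crtd])
        cD = km_estimate(t[crtd], e[crtd])
        for ent in arr_table(cP, cD, range(1, 12)):
            if ent.available:
                assert ent.significant == (not ent.ci_lo <= 0 <= ent.ci_hi)


class TestLogrank:
    def test_identical_arms(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, False, True, True]
        stat, p = logrank(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_strong_separation(self):
        rng = np.random.default_rng(5)
        tA = rng.exponential(1.0, 500)
        tB = rng.exponential(1 / 0.3, 500)
        _, p = logrank(tA, np.ones(500, bool), tB, np.ones(500, bool))
        assert p < 1e-3

    def test_agrees_with_univariable_cox_order_of_magnitude(self):
        cfg = synth.two_arm_config(3000, 0.7, seed=13)
        _, records, _ = synth.generate_cohort(cfg)
        t, e = apply_endpoint(records)
        crtd = (records["device"] == "CRT-D").to_numpy()
        _, p_lr = logrank(t[~crtd], e[~crtd], t[crtd], e[crtd])
        fit = cox_fit(t, e, pd.DataFrame({"crtd": crtd.astype(float)}))
        p_cox = fit.table.loc["crtd", "p"]
        if p_lr > 1e-12 and p_cox > 1e-12:
            assert abs(math.log10(p_lr) - math.log10(p_cox)) < 1.0


class TestCox:
    def test_recovers_simulated_hazard_ratio(self):
        cfg = synth.two_arm_config(20000, 0.83, seed=4)
        _, records, _ = synth.generate_cohort(cfg)
        t, e = apply_endpoint(records)
        crtd = (records["device"] == "CRT-D").astype(float)
        fit = cox_fit(t, e, pd.DataFrame({"crtd": crtd.to_numpy()}))
        assert 0.79 < fit.hazard_ratio("crtd") < 0.87

    def test_constant_covariate_dropped(self):
        cfg = synth.two_arm_config(500, 0.8, seed=2)
        _, records, _ = synth.generate_cohort(cfg)
        t, e = apply_endpoint(records)
        cov = pd.DataFrame({
            "crtd": (records["device"] == "CRT-D").astype(float).to_numpy(),
            "zeros": np.zeros(500),
        })
        with pytest.warns(UserWarning):
            fit = cox_fit(t, e, cov)
        assert fit.dropped_covariates == ["zeros"]
        assert "crtd" in fit.table.index

    def test_order_invariance(self):
        cfg = synth.two_arm_config(800, 0.7, seed=8)
        _, records, _ = synth.generate_cohort(cfg)
        t, e = apply_endpoint(records)
        cov = pd.DataFrame({"crtd": (records["device"] == "CRT-D").astype(float).to_numpy()})
        fit1 = cox_fit(t, e, cov)
        perm = np.random.default_rng(0).permutation(800)
        fit2 = cox_fit(t[perm], e[perm], cov.iloc[perm])
        assert fit1.table.loc["crtd", "coef"] == pytest.approx(
            fit2.table.loc["crtd", "coef"], abs=1e-8
        )

    def test_missing_covariates_error(self):
        cov = pd.DataFrame({"x": [1.0, np.nan, 0.0]})
        with pytest.raises(ValueError):
            cox_fit([1, 2, 3], [1, 0, 1], cov)

    def test_hr_matches_nelson_aalen_ratio(self):
        # 2-group exponential, no ties: exp(coef) ~ ratio of cumulative hazards
        cfg = synth.two_arm_config(10000, 0.6, seed=31, admin_censor_years=1e9)
        _, records, _ = synth.generate_cohort(cfg)
        t, e = apply_endpoint(records)
        crtd = (records["device"] == "CRT-D").to_numpy()
        fit = cox_fit(t, e, pd.DataFrame({"crtd": crtd.astype(float)}))
        from lifelines import NelsonAalenFitter

        na0 = NelsonAalenFitter().fit(t[~crtd], e[~crtd])
        na1 = NelsonAalenFitter().fit(t[crtd], e[crtd])
        horizon = np.quantile(t, 0.5)
        ratio = float(
            na1.cumulative_hazard_at_times(horizon).iloc[0]
            / na0.cumulative_hazard_at_times(horizon).iloc[0]
        )
        assert fit.hazard_ratio("crtd") == pytest.approx(ratio, rel=0.05)
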