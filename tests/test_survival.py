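import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from phenomapper import (
    apply_censoring,
    cox_fit,
    km_estimate,
    logrank,
    reverse_km_followup,
    subgroup_forest,
)
from phenomapper.survival import MULTIVARIABLE_PRESET, _efron_loglik

from .oracles import hand_km


class TestCensoringRules:
    def _raw(self, **cols):
        base = {"patient_id": [1], "upgrade_date": ["2010-01-01"],
                "death_date": [None]}
        base.update({k: [v] for k, v in cols.items()})
        return pd.DataFrame(base)

    def test_death_before_any_censoring_is_event(self):
        out = apply_censoring(self._raw(death_date="2014-03-15"))
        assert out.loc[0, "event"] == 1
        assert out.loc[0, "time_years"] == pytest.approx(4.2, abs=0.01)
        assert out.loc[0, "censor_reason"] == "none"

    def test_administrative_10y_censoring(self):
        out = apply_censoring(self._raw(death_date="2022-01-01"))
        assert out.loc[0, "event"] == 0
        assert out.loc[0, "time_years"] == pytest.approx(10.0)
        assert out.loc[0, "censor_reason"] == "admin_10y"

    def test_transplant_censors_later_death(self):
        out = apply_censoring(self._raw(transplant_date="2013-01-01",
                                        death_date="2015-01-01"))
        assert out.loc[0, "event"] == 0
        assert out.loc[0, "time_years"] == pytest.approx(3.0, abs=0.01)
        assert out.loc[0, "censor_reason"] == "transplant"

    def test_subsequent_upgrade_censors(self):
        out = apply_censoring(self._raw(subsequent_upgrade_date="2012-07-01"))
        assert out.loc[0, "censor_reason"] == "subsequent_upgrade"
        assert out.loc[0, "time_years"] == pytest.approx(2.5, abs=0.01)

    def test_alive_at_query_censored_there(self):
        out = apply_censoring(self._raw(), query_date="2016-01-01")
        assert out.loc[0, "censor_reason"] == "query_date"
        assert out.loc[0, "time_years"] == pytest.approx(6.0, abs=0.01)

    def test_earliest_rule_wins(self):
        out = apply_censoring(self._raw(transplant_date="2019-01-01",
                                        subsequent_upgrade_date="2012-01-01",
                                        death_date="2021-06-01"))
        assert out.loc[0, "censor_reason"] == "subsequent_upgrade"

    def test_negative_followup_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            apply_censoring(self._raw(), query_date="2009-01-01")


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # times 1+, 2, 3, 4+ with events at 2 and 3
        curve = km_estimate([1, 2, 3, 4], [0, 1, 1, 0])
        np.testing.assert_allclose(curve.times, [2, 3])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3])

    def test_no_events_flat_at_one(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(5.0) == 1.0

    def test_no_censoring_equals_empirical_survivor(self, rng):
        t = rng.exponential(5, size=200)
        curve = km_estimate(t, np.ones(200, int))
        for q in [1.0, 3.0, 7.0]:
            assert curve.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_matches_lifelines(self, rng):
        t = rng.exponential(5, size=300)
        e = (rng.random(300) < 0.7).astype(int)
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(curve.times).to_numpy()
        np.testing.assert_allclose(curve.survival, ref, atol=1e-10)
        ci = kmf.confidence_interval_survival_function_
        lo = np.interp(curve.times, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
        hi = np.interp(curve.times, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
        np.testing.assert_allclose(curve.ci_lower, lo, atol=1e-8)
        np.testing.assert_allclose(curve.ci_upper, hi, atol=1e-8)

    def test_curve_monotone_and_ci_bounded(self, rng):
        t = rng.exponential(3, 150)
        e = (rng.random(150) < 0.5).astype(int)
        c = km_estimate(t, e)
        assert (np.diff(c.survival) <= 1e-12).all()
        assert ((c.ci_lower >= 0) & (c.ci_upper <= 1)).all()
        assert (c.ci_lower <= c.survival + 1e-12).all()

    def test_oracle_hand_km_random(self, rng):
        t = np.round(rng.exponential(3, 60), 1)  # ties on purpose
        e = (rng.random(60) < 0.6).astype(int)
        ref = hand_km(list(t), list(e))
        c = km_estimate(t, e)
        for (tt, ss), ct, cs in zip(ref, c.times, c.survival):
            assert tt == ct and ss == pytest.approx(cs)


class TestReverseKM:
    def test_all_censored_at_ten(self):
        out = reverse_km_followup(np.full(20, 10.0), np.zeros(20, int))
        assert out["median"] == pytest.approx(10.0)

    def test_all_deaths_undefined_median(self):
        with pytest.warns(UserWarning, match="median"):
            out = reverse_km_followup(np.arange(1.0, 6.0), np.ones(5, int))
        assert np.isnan(out["median"])

    def test_mixed_case_matches_flipped_hand_km(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 0, 1, 0, 0, 0]
        ref = hand_km(t, [1 - x for x in e])
        out = reverse_km_followup(np.array(t, float), np.array(e))
        median_ref = next(tt for tt, ss in ref if ss <= 0.5)
        assert out["median"] == pytest.approx(median_ref)


class TestLogrank:
    def test_identical_groups_statistic_near_zero(self):
        t = np.array([1.0, 2, 3, 4, 5] * 2)
        e = np.array([1, 0, 1, 1, 0] * 2)
        g = np.array([0] * 5 + [1] * 5)
        out = logrank(t, e, g)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-10)
        assert out["p"] == pytest.approx(1.0)

    def test_matches_lifelines_three_groups(self, rng):
        t = rng.exponential(4, 240)
        g = rng.integers(0, 3, 240)
        t[g == 2] *= 0.5
        e = (rng.random(240) < 0.8).astype(int)
        out = logrank(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert out["statistic"] == pytest.approx(ref.test_statistic, rel=1e-8)
        assert out["p"] == pytest.approx(ref.p_value, rel=1e-6)
        assert out["df"] == 2

    def test_small_worked_example(self):
        # two groups; observed-expected table worked by hand:
        # A: times 1(death), 3(death); B: 2(death), 4(censor)
        t = np.array([1.0, 3.0, 2.0, 4.0])
        e = np.array([1, 1, 1, 0])
        g = np.array(["A", "A", "B", "B"])
        # deaths at t=1: risk 4 (2A,2B), E_A += 1/2
        # t=2: risk 3 (1A,2B), death in B, E_A += 1/3
        # t=3: risk 2 (1A,1B), death in A, E_A += 1/2
        out = logrank(t, e, g)
        O_A, E_A = out["observed"][0], out["expected"][0]
        assert O_A == pytest.approx(2.0)
        assert E_A == pytest.approx(0.5 + 1 / 3 + 0.5)

    def test_logrank_equals_cox_score_test_two_groups(self, rng):
        t = rng.exponential(3, 400)
        g = rng.integers(0, 2, 400)
        t[g == 1] *= 0.7
        e = np.ones(400, int)
        out = logrank(t, e, g)
        x = (g == 1).astype(float)[:, None]
        _, grad, hess = _efron_loglik(np.zeros(1), x - x.mean(), t, e)
        score_stat = float(grad @ np.linalg.solve(-hess, grad))
        assert out["statistic"] == pytest.approx(score_stat, rel=0.05)

    def test_group_with_zero_patients_rejected(self):
        with pytest.raises(ValueError):
            logrank(np.array([1.0, 2.0]), np.array([1, 1]), np.array([0, 0]))


class TestCox:
    def test_null_covariate_hr_near_one(self, rng):
        t = rng.exponential(5, 3000)
        e = np.ones(3000, int)
        x = rng.permutation(np.repeat([0.0, 1.0], 1500))[:, None]
        fit = cox_fit(t, e, x, names=["noise"])
        assert fit.ci_lower[0] < 1 < fit.ci_upper[0]
        assert fit.hr[0] == pytest.approx(1.0, abs=0.15)

    def test_two_group_exponential_true_hr_two(self, rng):
        n = 2000
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(1.0, n) / np.where(x == 1, 2.0, 1.0)
        fit = cox_fit(t, np.ones(n, int), x[:, None], names=["g"])
        assert 1.8 < fit.hr[0] < 2.2

    def test_matches_lifelines_with_ties(self, rng):
        n = 300
        X = rng.normal(size=(n, 3))
        t = np.ceil(rng.exponential(5, n) * np.exp(-0.5 * X[:, 0]))  # yearly ties
        e = (rng.random(n) < 0.7).astype(int)
        fit = cox_fit(t, e, X, names=["a", "b", "c"])
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = t, e
        cph = CoxPHFitter().fit(df, "T", "E")  # lifelines defaults to Efron ties
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-5)
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-4)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(np.array([1.0, 2, 3]), np.array([1, 1, 0]),
                    np.ones((3, 1)), names=["flat"])

    def test_separation_detected(self):
        # perfect separation: all deaths in one arm, huge effect diverges
        t = np.array([1.0, 2, 3, 10, 11, 12])
        e = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1, 1, 0, 0, 0])[:, None]
        with pytest.raises(ValueError):
            cox_fit(t, e, x, names=["arm"])

    def test_multivariable_preset_names(self):
        assert "device_type" in MULTIVARIABLE_PRESET
        assert len(MULTIVARIABLE_PRESET) == 9


@pytest.fixture(scope="module")
def forest_cohort():
    rng = np.random.default_rng(77)
    n = 4000
    df = pd.DataFrame({
        "ischemic_etiology": rng.integers(0, 2, n).astype(float),
        "age": rng.uniform(60, 95, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "nyha_34": rng.integers(0, 2, n).astype(float),
        "gfr": rng.uniform(20, 100, n),
        "af": rng.integers(0, 2, n).astype(float),
        "dm": rng.integers(0, 2, n).astype(float),
        "lvef": rng.uniform(15, 45, n),
        "device_type": rng.integers(0, 2, n).astype(float),
    })
    # protective device effect only in the ischemic stratum (HR 0.5)
    hazard = 0.2 * np.exp(np.log(0.5) * df.device_type * df.ischemic_etiology)
    df["time_years"] = np.minimum(rng.exponential(1 / hazard), 10.0)
    df["event"] = (df["time_years"] < 10.0).astype(int)
    return df


class TestSubgroupForest:
    @pytest.fixture()
    def cohort(self, forest_cohort):
        return forest_cohort

    def test_planted_effect_found_only_in_ischemic(self, cohort):
        tbl = subgroup_forest(cohort).set_index("stratum")
        isch = tbl.loc["ischemic"]
        non = tbl.loc["non-ischemic"]
        assert isch["ci_upper"] < 1.0
        assert non["ci_lower"] < 1.0 < non["ci_upper"]

    def test_strata_partition_cohort(self, cohort):
        tbl = subgroup_forest(cohort)
        for var, sub in tbl.groupby("variable"):
            assert sub["n"].sum() == len(cohort)

    def test_zero_event_stratum_undefined_not_raised(self):
        df = pd.DataFrame({
            "ischemic_etiology": [1.0] * 4 + [0.0] * 4,
            "age": [70.0] * 8, "sex": [1.0] * 8, "nyha_34": [0.0] * 8,
            "gfr": [50.0] * 8, "af": [0.0] * 8, "dm": [0.0] * 8,
            "lvef": [30.0] * 8,
            "device_type": [0.0, 1, 0, 1] * 2,
            "time_years": [5.0] * 8,
            "event": [0] * 4 + [1] * 4,
        })
        tbl = subgroup_forest(df).set_index("stratum")
        assert np.isnan(tbl.loc["ischemic", "hr"])
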