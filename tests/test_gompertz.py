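"""Gompertz proportional-hazard model: survival algebra, solvers, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gompertz as scipy_gompertz

import bioage_fmd as bf
from bioage_fmd.gompertz import GompertzPH


def model_from(lam, gamma):
    """Covariate-free model with hazard scale lam."""
    return bf.GompertzModel(betas={}, const=float(np.log(lam)), gamma=gamma)


class TestSurvival:
    def test_survival_is_one_at_time_zero(self):
        assert bf.survival_prob(model_from(0.01, 0.08), {}, 0.0) == pytest.approx(1.0, abs=0)

    def test_hand_value_s20(self):
        s = bf.survival_prob(model_from(0.01, 0.08), {}, 20.0)
        assert s == pytest.approx(np.exp(0.125 * (1 - np.e**1.6)), rel=1e-12)
        assert s == pytest.approx(0.6101, abs=1e-4)

    def test_matches_scipy_parametrization(self):
        """Same law as scipy.stats.gompertz with c = lam/gamma, scale = 1/gamma."""
        lam, gamma = 0.004, 0.11
        m = model_from(lam, gamma)
        for t in (0.5, 5.0, 17.0, 40.0):
            assert bf.survival_prob(m, {}, t) == pytest.approx(
                scipy_gompertz.sf(t, lam / gamma, scale=1 / gamma), rel=1e-12
            )

    def test_strictly_decreasing_on_grid(self):
        m = model_from(0.002, 0.1)
        s = bf.survival_prob(m, {}, np.linspace(0, 60, 200))
        assert np.all(np.diff(s) < 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            bf.survival_prob(model_from(0.01, 0.08), {}, -1.0)

    def test_covariates_enter_through_hazard_scale(self):
        m = bf.GompertzModel(betas={"age": 0.05, "bioage": 0.08}, const=-10.0, gamma=0.09)
        lam = np.exp(-10.0 + 0.05 * 50 + 0.08 * 45)
        assert m.hazard_scale({"age": 50, "bioage": 45}) == pytest.approx(lam, rel=1e-12)
        with pytest.raises(ValueError, match="bioage"):
            m.hazard_scale({"age": 50})


class TestMedianLifeExpectancy:
    def test_toy_closed_form_value(self):
        t = bf.median_remaining_le(model_from(0.001, 0.1), {})
        assert t == pytest.approx(10 * np.log(1 + 100 * np.log(2)), rel=1e-10)
        assert t == pytest.approx(42.53, abs=0.005)

    def test_numeric_solver_agrees_with_closed_form(self):
        """Randomized (lam, gamma) grid: the two routes match to 1e-8 years."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            lam = 10 ** rng.uniform(-4, -1.3)
            gamma = rng.uniform(0.02, 0.2)
            m = model_from(lam, gamma)
            t_num = bf.median_remaining_le(m, {}, method="numeric")
            t_cf = bf.median_remaining_le(m, {}, method="closed_form")
            assert abs(t_num - t_cf) < 1e-8
            assert bf.survival_prob(m, {}, t_num) == pytest.approx(0.5, abs=1e-10)

    def test_doubling_hazard_shortens_median(self):
        t1 = bf.median_remaining_le(model_from(0.001, 0.1), {})
        t2 = bf.median_remaining_le(model_from(0.002, 0.1), {})
        assert t2 < t1

    def test_plateau_above_half_raises(self):
        # gamma < 0: survival plateaus at exp(lam/gamma) which can exceed 0.5
        with pytest.raises(ValueError, match="never reaches"):
            bf.median_remaining_le(model_from(0.001, -0.1), {})


class TestMortalityRisk:
    def test_zero_horizon_zero_risk(self):
        assert bf.mortality_risk(model_from(0.01, 0.08), {}, horizon=0.0) == 0.0

    def test_twenty_year_hand_value(self):
        r = bf.mortality_risk(model_from(0.01, 0.08), {}, horizon=20.0)
        assert r == pytest.approx(0.3899, abs=1e-4)

    def test_risk_increases_with_bioage(self):
        m = bf.GompertzModel(betas={"age": 0.04, "bioage": 0.06}, const=-10.0, gamma=0.09)
        risks = [
            bf.mortality_risk(m, {"age": 55, "bioage": b}, 20.0) for b in (45, 55, 65)
        ]
        assert risks[0] < risks[1] < risks[2]
        assert all(0 <= r <= 1 for r in risks)

    def test_weight_model_with_zero_beta_matches_base(self):
        base = bf.GompertzModel(betas={"age": 0.04, "bioage": 0.06}, const=-10.0, gamma=0.09)
        wadj = bf.GompertzModel(
            betas={"age": 0.04, "bioage": 0.06, "weight": 0.0}, const=-10.0, gamma=0.09
        )
        cov = {"age": 55, "bioage": 50, "weight": 80.0}
        assert bf.mortality_risk(wadj, cov, 20.0) == bf.mortality_risk(base, cov, 20.0)
        assert bf.median_remaining_le(wadj, cov) == bf.median_remaining_le(base, cov)


class TestRelativeReduction:
    @pytest.mark.parametrize(
        "p0, p1, decimals, printed",
        [
            (11.25, 10.07, 1, 10.5),
            (2.30, 1.90, 1, 17.4),
            (4.54, 4.25, 1, 6.4),
            (0.50, 0.39, 0, 22.0),
            (0.23, 0.17, 0, 26.0),
        ],
    )
    def test_printed_risk_pairs(self, p0, p1, decimals, printed):
        assert bf.relative_reduction(p0, p1, decimals=decimals) == printed

    def test_no_change_is_zero(self):
        assert bf.relative_reduction(5.0, 5.0) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            bf.relative_reduction(0.0, 1.0)


class TestFitting:
    def test_parameter_recovery_modest_n(self):
        true = bf.GompertzModel(
            betas={"age": 0.05, "bioage": 0.08}, const=-13.0, gamma=0.09
        )
        rec = bf.simulate_survival_records(8000, true, seed=42)
        res = GompertzPH.from_records(rec).fit()
        est = dict(zip(res.param_names, res.params))
        # sampling error at n=8000 is ~2-3x larger than at the n=20,000
        # recovery check; allow 20% here
        for name, truth in [("age", 0.05), ("bioage", 0.08), ("const", -13.0), ("gamma", 0.09)]:
            assert abs(est[name] - truth) / abs(truth) < 0.20, name

    def test_standard_errors_cover_truth(self):
        true = bf.GompertzModel(
            betas={"age": 0.05, "bioage": 0.08}, const=-13.0, gamma=0.09
        )
        rec = bf.simulate_survival_records(8000, true, seed=3)
        res = GompertzPH.from_records(rec).fit()
        est = dict(zip(res.param_names, res.params))
        se = dict(zip(res.param_names, res.bse))
        for name, truth in [("age", 0.05), ("bioage", 0.08), ("gamma", 0.09)]:
            assert abs(est[name] - truth) < 4 * se[name], name

    def test_all_censored_raises(self):
        rec = pd.DataFrame(
            {"time": np.ones(100), "event": 0, "cause": "", "age": 50.0, "bioage": 50.0}
        )
        with pytest.raises(ValueError, match="10 events|no events"):
            bf.fit_gompertz_ph(rec)

    def test_single_cause_fit_equals_all_cause(self):
        true = bf.GompertzModel(betas={"age": 0.05, "bioage": 0.08}, const=-13.0, gamma=0.09)
        rec = bf.simulate_survival_records(3000, true, seed=9)
        rec["cause"] = np.where(rec["event"] == 1, "heart", "")
        m_all = bf.fit_gompertz_ph(rec)
        m_heart = bf.fit_gompertz_ph(rec, cause="heart")
        assert m_all.betas["bioage"] == pytest.approx(m_heart.betas["bioage"], abs=1e-6)
        assert m_all.gamma == pytest.approx(m_heart.gamma, abs=1e-6)

    def test_min_record_count_enforced(self):
        rec = pd.DataFrame(
            {"time": np.ones(10), "event": 1, "cause": "all", "age": 50.0, "bioage": 50.0}
        )
        with pytest.raises(ValueError, match="50 records"):
            bf.fit_gompertz_ph(rec)

    def test_summary_contains_all_parameters(self):
        true = bf.GompertzModel(betas={"age": 0.05, "bioage": 0.08}, const=-13.0, gamma=0.09)
        rec = bf.simulate_survival_records(2000, true, seed=5)
        text = GompertzPH.from_records(rec).fit().summary()
        for name in ("age", "bioage", "const", "gamma"):
            assert name in text


class TestCauseSpecific:
    @pytest.fixture(scope="class")
    def two_cause_records(self):
        """Two causes with true hazard scales in a 2:1 ratio."""
        rng = np.random.default_rng(23)
        n = 12000
        age = rng.uniform(40, 85, n)
        bioage = age + rng.normal(0, 5, n)
        lam_a = np.exp(-12.0 + 0.04 * age + 0.05 * bioage) * 2 / 3
        lam_b = lam_a / 2
        gamma = 0.09
        u = rng.uniform(1e-12, 1, (2, n))
        t_a = bf.sample_gompertz_event_time(lam_a, gamma, u[0])
        t_b = bf.sample_gompertz_event_time(lam_b, gamma, u[1])
        t = np.minimum(np.minimum(t_a, t_b), 23.0)
        event = (np.minimum(t_a, t_b) <= 23.0).astype(int)
        cause = np.where(t_a <= t_b, "heart", "cancer")
        return pd.DataFrame(
            {
                "time": t,
                "event": event,
                "cause": np.where(event == 1, cause, ""),
                "age": age,
                "bioage": bioage,
            }
        )

    def test_fitted_cause_risks_ordered_2_to_1(self, two_cause_records):
        models = {
            c: bf.fit_gompertz_ph(two_cause_records, cause=c) for c in ("heart", "cancer")
        }
        risks = bf.cause_specific_risk_suite(models, {"age": 60, "bioage": 60}, 20.0)
        assert risks["heart"] > risks["cancer"]
        # cumulative hazards should sit near the generative 2:1 ratio
        ch_heart = -np.log(1 - risks["heart"])
        ch_cancer = -np.log(1 - risks["cancer"])
        assert ch_heart / ch_cancer == pytest.approx(2.0, rel=0.15)

    def test_lower_bioage_reduces_every_cause_risk(self, two_cause_records):
        models = {
            c: bf.fit_gompertz_ph(two_cause_records, cause=c) for c in ("heart", "cancer")
        }
        hi = bf.cause_specific_risk_suite(models, {"age": 60, "bioage": 62}, 20.0)
        lo = bf.cause_specific_risk_suite(models, {"age": 60, "bioage": 55}, 20.0)
        assert all(lo[c] < hi[c] for c in models)

    def test_empty_suite_rejected(self):
        with pytest.raises(ValueError):
            bf.cause_specific_risk_suite({}, {"age": 60, "bioage": 60})
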