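"""Negative-control estimators: contracts and small-scale recovery."""

import math

import numpy as np
import pandas as pd
import pytest

import casecross as cc
from casecross import causal, clogit
from casecross.causal import NegativeControlError

from conftest import make_deaths, make_panel


class TestDifferenceCorrection:
    def test_worked_example_from_printed_percents(self):
        got = cc.corrected_percent_from_printed(0.73, -0.36, delta=10.0)
        assert round(got, 2) == 1.09

    def test_zero_lead_is_identity(self):
        beta = pd.Series({"e": 0.002, "l": 0.0})
        cov = pd.DataFrame(
            [[1e-6, 0.0], [0.0, 4e-7]], index=["e", "l"], columns=["e", "l"]
        )
        fit = clogit.FitResult(beta, cov, -1.0, 3, True, 100, 100)
        corr = cc.difference_correction(fit, "e", "l")
        assert corr.beta_corrected == fit.beta["e"]
        assert corr.variance == pytest.approx(1e-6 + 4e-7)

    def test_orthogonal_limit_reduces_to_exposure_variance(self):
        beta = pd.Series({"e": 0.002, "l": 0.001})
        cov = pd.DataFrame(
            [[1e-6, 0.0], [0.0, 1e-12]], index=["e", "l"], columns=["e", "l"]
        )
        fit = clogit.FitResult(beta, cov, -1.0, 3, True, 10, 10)
        corr = cc.difference_correction(fit, "e", "l")
        assert corr.variance == pytest.approx(1e-6, rel=1e-5)

    def test_labels_must_share_a_fit(self):
        beta = pd.Series({"e": 0.002})
        cov = pd.DataFrame([[1e-6]], index=["e"], columns=["e"])
        fit = clogit.FitResult(beta, cov, -1.0, 3, True, 10, 10)
        with pytest.raises(NegativeControlError, match="covariance"):
            cc.difference_correction(fit, "e", "lead_elsewhere")

    def test_independence_approximation_labelled(self):
        beta = pd.Series({"e": 0.002, "l": 0.001})
        cov = pd.DataFrame(
            [[1e-6, 5e-7], [5e-7, 1e-6]], index=["e", "l"], columns=["e", "l"]
        )
        fit = clogit.FitResult(beta, cov, -1.0, 3, True, 10, 10)
        dep = cc.difference_correction(fit, "e", "l")
        indep = cc.difference_correction(fit, "e", "l", independence_approximation=True)
        assert indep.independence_approximation
        assert indep.variance == pytest.approx(2e-6)
        assert dep.variance == pytest.approx(1e-6)


class TestNecFit:
    def test_requires_lead_columns(self, small_strata):
        no_leads = small_strata.select_features(
            [l for l in small_strata.feature_labels if "lead" not in l]
        )
        with pytest.raises(NegativeControlError, match="lead"):
            cc.nec_adjusted_fit(no_leads)

    def test_duplicated_lead_column_raises_collinearity(self):
        panel = make_panel("2010-05-20", "2010-07-10")
        deaths = make_deaths(["2010-06-16", "2010-06-10", "2010-06-22"])
        spec = cc.FeatureSpec(
            (
                cc.Feature("pm25", "ma", (0, 0), "pm25_ma00"),
                cc.Feature("pm25", "lag", 0, "pm25_dup"),
            )
        )
        strata = cc.assemble_strata(deaths, panel, spec)
        with pytest.raises(clogit.CollinearityError):
            clogit.fit(strata)


class TestNocFit:
    def test_zero_records_error(self, small_strata):
        empty = small_strata.subset(np.zeros(small_strata.n_strata, bool))
        with pytest.raises(Exception):
            causal.noc_fit(empty)

    def test_null_world_flag_true(self, small_world):
        cfg, panel, deaths, truth = small_world
        nafld = deaths[deaths["cause_class"] == "nafld_control"]
        strata = cc.assemble_strata(nafld, panel, cc.default_feature_spec())
        res = causal.noc_fit(strata)
        # no confounder in this world: the negative outcome should look null
        assert set(res.estimates) == {"pm25", "o3", "no2"}
        assert res.consistent_with_null


class TestSurrogate:
    def test_poisson_irls_recovers_known_model(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(20)
        n = 4000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        beta_true = np.array([0.5, 0.3, -0.2])
        mu = np.exp(beta_true[0] + beta_true[1] * x1 + beta_true[2] * x2)
        y = rng.poisson(mu)
        X = np.column_stack([np.ones(n), x1, x2])
        beta, cov = causal.poisson_irls(X, y, ["intercept", "x1", "x2"])
        se = np.sqrt(np.diag(cov))
        np.testing.assert_array_less(np.abs(beta - beta_true), 2.0 * se)
        # agreement with an independent GLM implementation
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(beta, ref.params, atol=1e-8)
        np.testing.assert_allclose(se, ref.bse, atol=1e-8)

    def test_all_zero_counts_error(self):
        panel = make_panel("2010-05-01", "2010-07-31")
        counts = panel[["date", "region"]].assign(count=0)
        with pytest.raises(NegativeControlError, match="zero"):
            causal.fit_surrogate(panel, counts)

    def test_constant_counts_intercept_only_gives_sample_mean(self):
        panel = make_panel("2010-05-01", "2010-07-31")
        counts = panel[["date", "region"]].assign(count=3)
        sur = causal.fit_surrogate(
            panel, counts, include_covariates=False, n_harmonics=0, include_region_effects=False
        )
        np.testing.assert_allclose(sur.values["w_hat"], 3.0, rtol=1e-6)

    def test_surrogate_nonnegative_and_covering(self, small_world):
        cfg, panel, deaths, _ = small_world
        counts = causal.aggregate_daily_counts(deaths, panel)
        sur = causal.fit_surrogate(panel, counts)
        assert (sur.values["w_hat"] >= 0).all()
        assert np.isfinite(sur.values["w_hat"]).all()


class TestTwoStage:
    def test_constant_surrogate_equals_nec_fit(self, small_world, small_strata):
        cfg, panel, deaths, _ = small_world
        sur = causal.SurrogateSeries(
            values=panel[["date", "region"]].assign(w_hat=2.5),
            coefficients=pd.Series({"intercept": math.log(2.5)}),
            description="constant",
        )
        nec = cc.nec_adjusted_fit(small_strata)
        fit, ests = cc.two_stage_fit(small_strata, sur, keep_leads=True)
        np.testing.assert_allclose(
            fit.beta.to_numpy(), nec.beta.to_numpy(), atol=1e-8
        )

    def test_coverage_gap_is_error(self, small_world, small_strata):
        cfg, panel, deaths, _ = small_world
        partial = panel.iloc[: len(panel) // 2]
        sur = causal.SurrogateSeries(
            values=partial[["date", "region"]].assign(w_hat=1.0),
            coefficients=pd.Series(dtype=float),
            description="partial",
        )
        with pytest.raises(NegativeControlError, match="cover"):
            cc.two_stage_fit(small_strata, sur)

    def test_deterministic(self, small_world, small_strata):
        cfg, panel, deaths, _ = small_world
        counts = causal.aggregate_daily_counts(deaths, panel)
        sur = causal.fit_surrogate(panel, counts)
        f1, e1 = cc.two_stage_fit(small_strata, sur)
        f2, e2 = cc.two_stage_fit(small_strata, sur)
        assert f1.beta.equals(f2.beta)
        assert e1["pm25"].percent == e2["pm25"].percent


class TestNecSimulation:
    def test_lead_estimates_null_when_unconfounded(self):
        """Without a confounder the lead-1 coefficients centre on zero."""
        zs = []
        for rep in range(6):
            cfg = cc.SimulationConfig(
                n_regions=8,
                start_date="2010-01-01",
                end_date="2010-12-31",
                baseline_rate=1.0,
                seed=300 + rep,
            )
            panel = cc.simulate_panel(cfg)
            deaths, _ = cc.simulate_deaths(panel, cfg)
            main = deaths[deaths["cause_class"] != "nafld_control"]
            strata = cc.assemble_strata(main, panel, cc.default_feature_spec())
            fit = cc.nec_adjusted_fit(strata)
            est = clogit.percent_increase(fit, "pm25_lead1")
            zs.append(est.beta / est.se)
        # mean z of 6 independent replicates ~ N(0, 1/sqrt(6)) under the null
        assert abs(np.mean(zs)) < 3.0 / math.sqrt(6)
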