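"""Conditional-logistic likelihood, fitting and effect transformation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casecross import clogit
from casecross.clogit import CollinearityError

from conftest import random_strata


def naive_loglik(beta, strata):
    """Independent brute-force enumeration of the stratum probability ratio."""
    ll = 0.0
    beta = np.asarray(beta, float)
    for i in range(strata.n_strata):
        rows = strata.X[strata.starts[i] : strata.starts[i] + strata.counts[i]]
        terms = [math.exp(float(r @ beta)) for r in rows]
        ll += math.log(terms[0] / sum(terms))
    return ll


class TestLoglik:
    def test_zero_beta_closed_form(self):
        rng = np.random.default_rng(0)
        s = random_strata(rng)
        expected = -sum(math.log(int(m)) for m in s.counts)
        assert clogit.loglik(np.zeros(s.X.shape[1]), s) == pytest.approx(expected, abs=1e-12)

    def test_two_strata_frozen_example(self):
        """Hand-built 2x2 problem against values frozen from direct enumeration."""
        from casecross.design import StratumSet

        s = StratumSet(
            X=np.array([[1.0], [0.0], [0.5], [2.0]]),
            feature_labels=["x"],
            starts=np.array([0, 2]),
            counts=np.array([2, 2]),
            row_dates=np.zeros(4, "datetime64[s]"),
            meta=pd.DataFrame({"stratum_id": [0, 1]}),
        )
        assert clogit.loglik(np.array([0.3]), s) == pytest.approx(-1.497604190465982, abs=1e-12)
        assert clogit.loglik(np.array([-1.2]), s) == pytest.approx(-1.6162600778641054, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_and_fd_gradient(self, seed):
        rng = np.random.default_rng(seed)
        s = random_strata(rng)
        beta = rng.normal(scale=0.5, size=s.X.shape[1])
        ll, g = clogit.loglik(beta, s, gradient=True)
        assert ll == pytest.approx(naive_loglik(beta, s), rel=1e-10)
        for j in range(len(beta)):
            e = np.zeros_like(beta)
            e[j] = 1e-6
            fd = (naive_loglik(beta + e, s) - naive_loglik(beta - e, s)) / 2e-6
            assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25)
    def test_stratum_constant_shift_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = random_strata(rng)
        beta = rng.normal(scale=0.7, size=s.X.shape[1])
        shifts = rng.normal(scale=5.0, size=s.n_strata)
        X2 = s.X.copy()
        X2[:, 0] += np.repeat(shifts, s.counts)
        from dataclasses import replace

        s2 = replace(s, X=X2)
        assert clogit.loglik(beta, s2) == pytest.approx(clogit.loglik(beta, s), rel=1e-9)

    def test_nonfinite_feature_names_stratum(self):
        rng = np.random.default_rng(3)
        s = random_strata(rng)
        s.X[s.starts[2] + 1, 0] = np.nan
        with pytest.raises(ValueError, match="strata"):
            clogit.loglik(np.zeros(s.X.shape[1]), s)


class TestFit:
    def test_one_to_one_matching_equals_difference_logistic(self):
        """1:1 strata reduce to no-intercept logistic regression on differences."""
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        n = 300
        X = rng.normal(size=(2 * n, 2))
        from casecross.design import StratumSet

        s = StratumSet(
            X=X,
            feature_labels=["a", "b"],
            starts=np.arange(0, 2 * n, 2),
            counts=np.full(n, 2),
            row_dates=np.zeros(2 * n, "datetime64[s]"),
            meta=pd.DataFrame({"stratum_id": np.arange(n)}),
        )
        fit = clogit.fit(s)
        diffs = X[0::2] - X[1::2]
        oracle = sm.Logit(np.ones(n), diffs).fit(disp=0)
        np.testing.assert_allclose(fit.beta.to_numpy(), oracle.params, atol=1e-6)

    def test_likelihood_at_optimum_beats_neighbours(self):
        rng = np.random.default_rng(5)
        s = random_strata(rng, n_strata=(30, 31))
        fit = clogit.fit(s)
        b = fit.beta.to_numpy()
        ll = clogit.loglik(b, s)
        for j in range(len(b)):
            for eps in (-1e-4, 1e-4):
                bb = b.copy()
                bb[j] += eps
                assert clogit.loglik(bb, s) <= ll + 1e-12

    def test_referent_reordering_invariance(self):
        rng = np.random.default_rng(8)
        s = random_strata(rng)
        fit1 = clogit.fit(s)
        # reverse referent rows within each stratum (case row stays first)
        X2 = s.X.copy()
        for i in range(s.n_strata):
            a, c = s.starts[i], s.counts[i]
            X2[a + 1 : a + c] = X2[a + 1 : a + c][::-1]
        from dataclasses import replace

        fit2 = clogit.fit(replace(s, X=X2))
        np.testing.assert_allclose(fit1.beta.to_numpy(), fit2.beta.to_numpy(), atol=1e-10)

    def test_stratum_constant_shift_leaves_estimate(self):
        rng = np.random.default_rng(9)
        s = random_strata(rng)
        fit1 = clogit.fit(s)
        X2 = s.X.copy()
        X2[:, 0] += np.repeat(rng.normal(scale=4.0, size=s.n_strata), s.counts)
        from dataclasses import replace

        fit2 = clogit.fit(replace(s, X=X2))
        np.testing.assert_allclose(fit1.beta.to_numpy(), fit2.beta.to_numpy(), atol=1e-7)

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(10)
        s = random_strata(rng, k=(2, 3))
        s.X[:, 1] = 2.0 * s.X[:, 0]
        with pytest.raises(CollinearityError, match="x0|x1"):
            clogit.fit(s)

    def test_stratum_constant_feature_rejected(self):
        rng = np.random.default_rng(11)
        s = random_strata(rng, k=(2, 3))
        s.X[:, 0] = np.repeat(rng.normal(size=s.n_strata), s.counts)
        with pytest.raises(CollinearityError, match="x0"):
            clogit.fit(s)

    def test_covariance_symmetric_psd(self):
        rng = np.random.default_rng(13)
        s = random_strata(rng, k=(3, 4))
        fit = clogit.fit(s)
        V = fit.cov.to_numpy()
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.linalg.eigvalsh(V).min() > 0


class TestPercentIncrease:
    def test_zero_beta_zero_percent(self):
        est = clogit.effect_from_beta(0.0, 0.01, "pm25", 10.0)
        assert est.percent == 0.0
        assert est.ci_low < 0 < est.ci_high
        assert est.ci_low == pytest.approx(-est.ci_high / (1 + est.ci_high / 100), rel=1e-6)

    def test_planted_percent_roundtrip(self):
        beta = math.log(1.0073) / 10.0
        est = clogit.effect_from_beta(beta, 0.001, "pm25", 10.0)
        assert round(est.percent, 2) == 0.73

    def test_monotone_in_beta(self):
        betas = np.linspace(-0.01, 0.01, 21)
        pcts = [clogit.effect_from_beta(b, 0.001, "x", 10.0).percent for b in betas]
        assert all(a < b for a, b in zip(pcts, pcts[1:]))

    def test_ci_ordering_and_sign(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            b, se = rng.normal(scale=0.01), abs(rng.normal(scale=0.01)) + 1e-6
            est = clogit.effect_from_beta(b, se, "x", 10.0)
            assert est.ci_low <= est.percent <= est.ci_high
            assert np.sign(est.percent) == np.sign(b)

    def test_unknown_label_errors(self):
        rng = np.random.default_rng(2)
        fit = clogit.fit(random_strata(rng))
        with pytest.raises(KeyError, match="nope"):
            clogit.percent_increase(fit, "nope")
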