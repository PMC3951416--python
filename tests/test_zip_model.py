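"""ZIP likelihood, design matrices and the joint log-posterior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ovizip.zip_model import (
    DesignMatrix,
    PriorSpec,
    ZipParameters,
    build_design_matrix,
    log_likelihood,
    log_posterior,
    zip_log_pmf,
    zip_moments,
    zip_rvs,
)


class TestZipLogPmf:
    def test_no_inflation_equals_poisson(self):
        y = np.arange(0, 20)
        np.testing.assert_allclose(
            zip_log_pmf(y, 3.7, 0.0), stats.poisson.logpmf(y, 3.7), rtol=1e-12
        )

    def test_zero_case_direct_value(self):
        assert zip_log_pmf(0, 2.0, 0.5) == pytest.approx(np.log(0.5 + 0.5 * np.exp(-2)))

    @given(
        lam=st.floats(0.01, 50.0),
        rho=st.floats(0.0, 0.99),
    )
    @settings(deadline=None, max_examples=50)
    def test_normalizes_to_one(self, lam, rho):
        y = np.arange(0, int(lam + 20 * np.sqrt(lam) + 20))
        total = np.exp(zip_log_pmf(y, lam, rho)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_stable_at_large_lambda(self):
        val = zip_log_pmf(0, 1e4, 0.3)
        assert np.isfinite(val)
        assert val == pytest.approx(np.log(0.3), abs=1e-8)

    def test_rho_one_with_positive_count_is_neg_inf(self):
        assert zip_log_pmf(3, 2.0, 1.0) == -np.inf

    @given(lam=st.floats(0.1, 20.0), r1=st.floats(0.0, 0.98), r2=st.floats(0.0, 0.98))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_rho(self, lam, r1, r2):
        lo, hi = sorted((r1, r2))
        # more inflation -> zeros more likely, positives less likely
        assert zip_log_pmf(0, lam, hi) >= zip_log_pmf(0, lam, lo)
        assert zip_log_pmf(2, lam, hi) <= zip_log_pmf(2, lam, lo)


class TestZipMoments:
    @pytest.mark.parametrize(
        "lam,rho,mean,od",
        [(5.0, 0.0, 5.0, 1.0), (10.0, 1.0, 0.0, 11.0), (10.0, 0.5, 5.0, 6.0)],
    )
    def test_closed_forms(self, lam, rho, mean, od):
        m, v, o = zip_moments(lam, rho)
        assert m == pytest.approx(mean)
        assert o == pytest.approx(od)
        assert v == pytest.approx(mean * od)

    def test_simulation_matches_closed_form(self, rng):
        lam, rho, n = 10.0, 0.5, 100_000
        draws = zip_rvs(lam, rho, rng, size=n)
        mean, var, _ = zip_moments(lam, rho)
        # moments of the pmf give the exact sampling SEs
        y = np.arange(0, 200)
        p = np.exp(zip_log_pmf(y, lam, rho))
        mu4 = np.sum(p * (y - mean) ** 4)
        se_mean = np.sqrt(var / n)
        se_var = np.sqrt((mu4 - var**2) / n)
        assert abs(draws.mean() - mean) < 3 * se_mean
        assert abs(draws.var(ddof=1) - var) < 3 * se_var


class TestDesignMatrix:
    def test_variant_a_excludes_own_presence(self, records_frame):
        data = build_design_matrix(records_frame, "ALB", variant="A")
        assert data.x_names == ["intercept", "month", "AEG_present", "CQ_present"]
        assert data.w_names == ["zi_intercept", "zi_month"]

    def test_month_coding(self, records_frame):
        data = build_design_matrix(records_frame, "CQ", variant="A")
        month = data.X[:, data.x_names.index("month")]
        early = data.row_meta["season"] == "early"
        assert (month[early.to_numpy()] == 0).all()
        assert (month[~early.to_numpy()] == 1).all()

    def test_variant_b_has_per_season_pairs(self, small_study):
        from ovizip.landcover import prepare_covariates

        frame = small_study.records_frame()
        cols = [c for c in small_study.profiles.columns if c.endswith("_200")]
        cov, _ = prepare_covariates(small_study.profiles, columns=cols)
        # keep every class for the design regardless of screening outcome
        for c in cols:
            if c not in cov.columns:
                cov[c] = (
                    small_study.profiles[c] - small_study.profiles[c].mean()
                ) / small_study.profiles[c].std(ddof=0)
        data = build_design_matrix(frame, "AEG", variant="B", covariates=cov, scale=200)
        assert len(data.x_names) == 9  # intercept + 4 covariates x 2 seasons
        for name in ("cemetery", "wetland", "high_intensity_developed"):
            assert f"{name}_early" in data.x_names
            assert f"{name}_late" in data.x_names
        assert "month" not in data.x_names

    def test_missing_covariates_rejected(self, records_frame):
        with pytest.raises(ValueError, match="variant B"):
            build_design_matrix(records_frame, "AEG", variant="B")


class TestLogPosterior:
    def _params(self, data, beta=None, sigma2=1.0):
        return ZipParameters(
            beta=np.zeros(data.X.shape[1]) if beta is None else np.asarray(beta, float),
            gamma=np.array([-0.5, 0.3]),
            alpha=np.zeros(data.n_cities),
            sigma2=sigma2,
        )

    def test_flat_prior_limit_is_likelihood_difference(self, intercept_only_design):
        data = intercept_only_design
        priors = PriorSpec(coef_variance=1e12)
        p1 = self._params(data, beta=[0.5])
        p2 = self._params(data, beta=[1.2])
        dlp = log_posterior(p1, data, priors) - log_posterior(p2, data, priors)
        dll = log_likelihood(p1, data) - log_likelihood(p2, data)
        assert dlp == pytest.approx(dll, abs=1e-6)

    def test_term_by_term_hand_sum(self):
        import pandas as pd

        y = np.array([0, 2, 1, 0])
        n = 4
        data = DesignMatrix(
            y=y,
            X=np.ones((n, 1)),
            W=np.ones((n, 1)),
            city_index=np.zeros(n, dtype=int),
            x_names=["intercept"],
            w_names=["zi_intercept"],
            row_meta=pd.DataFrame(
                {"site_id": list("abcd"), "city_id": "c", "site_class": "urban", "season": "early"}
            ),
            cities=["c"],
        )
        beta0, gamma0, alpha0, sigma2 = 0.4, -0.3, 0.1, 0.8
        params = ZipParameters(
            beta=np.array([beta0]),
            gamma=np.array([gamma0]),
            alpha=np.array([alpha0]),
            sigma2=sigma2,
        )
        priors = PriorSpec()
        lam = np.exp(beta0 + alpha0)
        rho = 1 / (1 + np.exp(-gamma0))
        expected = 0.0
        for yi in y:
            if yi == 0:
                expected += np.log(rho + (1 - rho) * np.exp(-lam))
            else:
                expected += (
                    np.log(1 - rho)
                    + yi * np.log(lam)
                    - lam
                    - np.log(float(math.factorial(yi)))
                )
        expected += stats.norm.logpdf(beta0, 0, np.sqrt(1000.0))
        expected += stats.norm.logpdf(gamma0, 0, np.sqrt(1000.0))
        expected += stats.norm.logpdf(alpha0, 0, np.sqrt(sigma2))
        expected += stats.invgamma.logpdf(sigma2, 0.01, scale=0.01)
        assert log_posterior(params, data, priors) == pytest.approx(expected, rel=1e-12)

    def test_prior_term_maximized_at_zero_beta(self, intercept_only_design):
        data = intercept_only_design
        priors = PriorSpec()
        at_zero = log_posterior(self._params(data, beta=[0.0]), data, priors) - log_likelihood(
            self._params(data, beta=[0.0]), data
        )
        away = log_posterior(self._params(data, beta=[2.0]), data, priors) - log_likelihood(
            self._params(data, beta=[2.0]), data
        )
        assert at_zero > away

    def test_outside_support_returns_neg_inf(self, intercept_only_design):
        params = self._params(intercept_only_design, sigma2=-1.0)
        assert log_posterior(params, intercept_only_design, PriorSpec()) == -np.inf

    def test_dimension_mismatch_raises(self, intercept_only_design):
        params = ZipParameters(
            beta=np.zeros(3), gamma=np.zeros(2), alpha=np.zeros(1), sigma2=1.0
        )
        with pytest.raises(ValueError, match="dimensions"):
            log_posterior(params, intercept_only_design, PriorSpec())
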