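"""Model comparison and coefficient interpretation.

The ZIP fit is judged against the plain Poisson reference (same regression,
``rho`` fixed at 0) on three axes: DIC (differences above 5 units are
treated as decisive), the proportion of zeros, and the overdispersion index
``OD.i = Var(y) / E(y)`` — each computed from the observed counts and from
posterior-predictive replicates. Deviance is ``-2`` times the *marginal*
log-likelihood (latent suitability integrated out) so the two models'
deviances live on the same scale.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .mcmc import ModelFit, PosteriorDraws
from .zip_model import DesignMatrix, zip_rvs

#: DIC difference treated as a decisive model preference
DIC_DECISION_THRESHOLD = 5.0


def overdispersion_index(y) -> float:
    """Sample variance over sample mean (``Var(y)/E(y)``, ddof 1).

    Equals 1 in expectation for Poisson data and ``1 + rho * lambda`` for
    ZIP data with constant rate.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty count vector")
    mean = y.mean()
    if mean == 0:
        raise ValueError("overdispersion index undefined for all-zero counts")
    return float(y.var(ddof=1) / mean)


class DicResult(NamedTuple):
    dic: float
    p_d: float
    d_bar: float


def dic(deviance_draws, deviance_at_posterior_mean: float) -> DicResult:
    """Deviance information criterion.

    ``Dbar`` is the posterior mean deviance, ``pD = Dbar - D(theta_bar)``
    the effective number of parameters, and ``DIC = Dbar + pD``.
    """
    deviance_draws = np.asarray(deviance_draws, dtype=float)
    if deviance_draws.size == 0:
        raise ValueError("no deviance draws")
    d_bar = float(deviance_draws.mean())
    p_d = d_bar - float(deviance_at_posterior_mean)
    return DicResult(dic=d_bar + p_d, p_d=p_d, d_bar=d_bar)


def _draw_params(draws: PosteriorDraws, data: DesignMatrix, idx):
    """lam and rho row-vectors for a set of flattened draw indices."""
    beta = draws.beta.reshape(-1, draws.beta.shape[2])[idx]
    gamma = draws.gamma.reshape(-1, draws.gamma.shape[2])[idx]
    alpha = draws.alpha.reshape(-1, draws.alpha.shape[2])[idx]
    lam = np.exp(beta @ data.X.T + alpha[:, data.city_index])
    if draws.zero_inflated:
        from scipy.special import expit

        rho = expit(gamma @ data.W.T)
    else:
        rho = np.zeros_like(lam)
    return lam, rho


def fit_deviance(fit: ModelFit) -> tuple[np.ndarray, float]:
    """Per-draw deviances and the deviance at the posterior-mean parameters."""
    dev_draws = -2.0 * fit.draws.loglik.ravel()
    mean_beta = fit.draws.beta.reshape(-1, fit.draws.beta.shape[2]).mean(axis=0)
    mean_gamma = fit.draws.gamma.reshape(-1, fit.draws.gamma.shape[2]).mean(axis=0)
    mean_alpha = fit.draws.alpha.reshape(-1, fit.draws.alpha.shape[2]).mean(axis=0)
    from scipy.special import expit

    from .zip_model import zip_log_pmf

    lam = np.exp(fit.data.X @ mean_beta + mean_alpha[fit.data.city_index])
    rho = expit(fit.data.W @ mean_gamma) if fit.zero_inflated else np.zeros_like(lam)
    d_hat = -2.0 * float(np.sum(zip_log_pmf(fit.data.y, lam, rho)))
    return dev_draws, d_hat


def fit_dic(fit: ModelFit) -> DicResult:
    """DIC of a fitted model from its stored marginal log-likelihood draws."""
    dev_draws, d_hat = fit_deviance(fit)
    return dic(dev_draws, d_hat)


def posterior_predictive_zero_fraction(
    draws: PosteriorDraws,
    data: DesignMatrix,
    rng: np.random.Generator,
    max_draws: int = 500,
) -> dict:
    """Zero fraction of posterior-predictive replicate responses.

    For each retained draw (subsampled to ``max_draws``) a full replicate
    response vector is simulated from the fitted model; the observed zero
    fraction is reported alongside the predictive mean and 95% interval.
    """
    n_total = draws.beta.shape[0] * draws.beta.shape[1]
    idx = (
        np.arange(n_total)
        if n_total <= max_draws
        else rng.choice(n_total, size=max_draws, replace=False)
    )
    lam, rho = _draw_params(draws, data, idx)
    y_rep = zip_rvs(lam, rho, rng)
    fractions = (y_rep == 0).mean(axis=1)
    lo, hi = np.percentile(fractions, [2.5, 97.5])
    return {
        "observed": float(np.mean(data.y == 0)),
        "predicted_mean": float(fractions.mean()),
        "predicted_q2.5": float(lo),
        "predicted_q97.5": float(hi),
        "fractions": fractions,
    }


def posterior_predictive_overdispersion(
    draws: PosteriorDraws,
    data: DesignMatrix,
    rng: np.random.Generator,
    max_draws: int = 500,
) -> dict:
    """Overdispersion index of posterior-predictive replicates."""
    n_total = draws.beta.shape[0] * draws.beta.shape[1]
    idx = (
        np.arange(n_total)
        if n_total <= max_draws
        else rng.choice(n_total, size=max_draws, replace=False)
    )
    lam, rho = _draw_params(draws, data, idx)
    y_rep = zip_rvs(lam, rho, rng)
    means = y_rep.mean(axis=1)
    ok = means > 0
    od = np.full(len(means), np.nan)
    od[ok] = y_rep[ok].var(axis=1, ddof=1) / means[ok]
    return {
        "observed": overdispersion_index(data.y),
        "predicted_mean": float(np.nanmean(od)),
    }


def compare_models(
    fit_poisson: ModelFit,
    fit_zip: ModelFit,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """One comparison row: zero fractions, OD, DIC difference, preference.

    ``delta_dic`` is DIC(Poisson) - DIC(ZIP): positive values favour the
    zero-inflated model; the preference is declared only past the 5-unit
    rule.
    """
    if fit_poisson.data.n_obs != fit_zip.data.n_obs or not np.array_equal(
        fit_poisson.data.y, fit_zip.data.y
    ):
        raise ValueError("fits to compare must share the same response data")
    rng = rng or np.random.default_rng(0)
    dic_p = fit_dic(fit_poisson)
    dic_z = fit_dic(fit_zip)
    zero_p = posterior_predictive_zero_fraction(fit_poisson.draws, fit_poisson.data, rng)
    zero_z = posterior_predictive_zero_fraction(fit_zip.draws, fit_zip.data, rng)
    od_p = posterior_predictive_overdispersion(fit_poisson.draws, fit_poisson.data, rng)
    od_z = posterior_predictive_overdispersion(fit_zip.draws, fit_zip.data, rng)
    delta = dic_p.dic - dic_z.dic
    if delta > DIC_DECISION_THRESHOLD:
        preferred = "ZIP"
    elif delta < -DIC_DECISION_THRESHOLD:
        preferred = "Poisson"
    else:
        preferred = "none"
    return pd.Series(
        {
            "species": fit_zip.data.species,
            "zeros_observed": zero_z["observed"],
            "zeros_poisson": zero_p["predicted_mean"],
            "zeros_zip": zero_z["predicted_mean"],
            "od_observed": od_z["observed"],
            "od_poisson": od_p["predicted_mean"],
            "od_zip": od_z["predicted_mean"],
            "dic_poisson": dic_p.dic,
            "dic_zip": dic_z.dic,
            "delta_dic": delta,
            "preferred": preferred,
        }
    )


def coef_to_percent_change(b: float) -> float:
    """Percent change in relative abundance implied by a log-scale coefficient.

    ``(exp(b) - 1) * 100``: the multiplicative effect of a one-unit
    covariate change (e.g. competitor present vs absent) on the Poisson
    mean, expressed as a percentage.
    """
    b = float(b)
    if not np.isfinite(b):
        raise ValueError("coefficient must be finite")
    return float(np.expm1(b) * 100.0)
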