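"""Metropolis-within-Gibbs sampler for the hierarchical ZIP regression.

The sampler augments the data with the latent site-suitability indicator
``z`` (``z = 1`` means the observation is governed by the Poisson state;
any positive count forces ``z = 1``). Each iteration then

1. redraws ``z`` at the zero-count rows from its exact Bernoulli
   conditional,
2. updates the abundance coefficients ``beta`` (one block) and the
   zero-inflation coefficients ``gamma`` (one block) by Gaussian
   random-walk Metropolis against their conditional posteriors given ``z``,
3. updates each city intercept ``alpha_c`` by scalar random-walk
   Metropolis, and
4. draws the city-effect variance ``sigma2`` exactly from its conjugate
   inverse-gamma full conditional.

Proposal scales adapt toward a ~30% acceptance rate during burn-in only,
so post-burn-in transitions preserve detailed balance. Chains use
independent substreams spawned from one master seed: results are bitwise
reproducible and adding chains never perturbs earlier ones. Recorded
per-draw quantities (the marginal log-likelihood, with ``z`` integrated
out, and the mean suitability probability) feed DIC and the "Presence"
summary downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .zip_model import DesignMatrix, PriorSpec, ZipParameters, zip_log_pmf

_ADAPT_WINDOW = 50
_TARGET_ACCEPT = 0.30


@dataclass
class SamplerConfig:
    """MCMC run settings.

    Defaults (3 chains of 20,000 iterations, 5,000 burn-in, thinning 5) are
    deliberately generous for datasets of a few hundred site-seasons;
    smaller settings are fine for simulation studies.
    """

    n_chains: int = 3
    n_iter: int = 20_000
    n_burnin: int = 5_000
    thin: int = 5
    seed: int = 0
    proposal_scales: dict[str, float] = field(
        default_factory=lambda: {"beta": 0.1, "gamma": 0.3, "alpha": 0.3}
    )
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("at least one chain required")
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if any(s <= 0 for s in self.proposal_scales.values()):
            raise ValueError("proposal scales must be positive")


@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned draws from all chains.

    Parameter draws are stacked as ``(n_chains, n_kept, dim)`` arrays;
    ``loglik`` holds the marginal ZIP log-likelihood of each kept draw and
    ``presence`` the mean of ``1 - rho_is`` over rows.
    """

    beta: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    sigma2: np.ndarray
    loglik: np.ndarray
    presence: np.ndarray
    param_names: list[str]
    acceptance: dict[str, float]
    zero_inflated: bool
    hierarchical: bool

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    def stacked(self) -> np.ndarray:
        """All scalar parameters as one (n_chains, n_kept, n_params) array."""
        parts = [self.beta]
        if self.zero_inflated:
            parts.append(self.gamma)
        if self.hierarchical:
            parts.append(self.alpha)
            parts.append(self.sigma2[..., None])
        return np.concatenate(parts, axis=2)

    def flat(self) -> np.ndarray:
        arr = self.stacked()
        return arr.reshape(-1, arr.shape[2])

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws (chain, iteration, one column per parameter)."""
        arr = self.stacked()
        n_chains, n_kept, _ = arr.shape
        df = pd.DataFrame(arr.reshape(-1, arr.shape[2]), columns=self.param_names)
        df.insert(0, "iteration", np.tile(np.arange(n_kept), n_chains))
        df.insert(0, "chain", np.repeat(np.arange(n_chains), n_kept))
        return df


@dataclass
class ModelFit:
    """A fitted model: data, draws and the summary table."""

    data: DesignMatrix
    draws: PosteriorDraws
    summary: pd.DataFrame
    config: SamplerConfig
    priors: PriorSpec

    @property
    def zero_inflated(self) -> bool:
        return self.draws.zero_inflated

    def max_rhat(self) -> float:
        return float(self.summary["rhat"].max())


def update_latent_suitability(y, lam, rho, rng: np.random.Generator) -> np.ndarray:
    """Exact conditional draw of the suitability indicator.

    Positive counts force ``z = 1``; at zeros,
    ``P(z = 1) = (1 - rho) e^{-lam} / (rho + (1 - rho) e^{-lam})``.
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), lam.shape)
    poisson_zero = (1.0 - rho) * np.exp(-lam)
    p1 = poisson_zero / (rho + poisson_zero)
    z = rng.random(lam.shape) < p1
    z[y > 0] = True
    return z


def _poisson_loglik(y, eta, z):
    """Poisson log-likelihood over suitable rows, dropping the y! constant."""
    return float(np.sum(y[z] * eta[z] - np.exp(eta[z])))


def _run_chain(data, priors, config, seed_seq, zero_inflated, hierarchical):
    rng = np.random.default_rng(seed_seq)
    y, X, W, ci = data.y, data.X, data.W, data.city_index
    n, p = X.shape
    q = W.shape[1]
    n_city = data.n_cities
    city_rows = [np.flatnonzero(ci == c) for c in range(n_city)]
    coef_prec = 1.0 / priors.coef_variance

    beta = np.zeros(p)
    gamma = np.zeros(q)
    alpha = np.zeros(n_city)
    sigma2 = 1.0
    # init: suitable wherever the count is positive, unsuitable at zeros
    z = y > 0 if zero_inflated else np.ones(n, dtype=bool)

    eta_x = X @ beta
    eta_w = W @ gamma
    scales = dict(config.proposal_scales)
    accept = {"beta": 0, "gamma": 0, "alpha": 0}
    window = {"beta": 0, "gamma": 0, "alpha": 0}
    n_kept = (config.n_iter - config.n_burnin) // config.thin
    out = {
        "beta": np.empty((n_kept, p)),
        "gamma": np.empty((n_kept, q)),
        "alpha": np.empty((n_kept, n_city)),
        "sigma2": np.empty(n_kept),
        "loglik": np.empty(n_kept),
        "presence": np.empty(n_kept),
    }
    kept = 0

    for it in range(config.n_iter):
        offset = alpha[ci]
        if zero_inflated:
            lam = np.exp(eta_x + offset)
            rho = special.expit(eta_w)
            z = update_latent_suitability(y, lam, rho, rng)

        # beta block: Poisson likelihood on suitable rows + N(0, v) prior
        cur_ll = _poisson_loglik(y, eta_x + offset, z)
        cur_lp = -0.5 * coef_prec * float(beta @ beta)
        prop = beta + scales["beta"] * rng.standard_normal(p)
        prop_eta = X @ prop
        prop_ll = _poisson_loglik(y, prop_eta + offset, z)
        prop_lp = -0.5 * coef_prec * float(prop @ prop)
        if np.log(rng.random()) < prop_ll + prop_lp - cur_ll - cur_lp:
            beta, eta_x = prop, prop_eta
            accept["beta"] += 1
            window["beta"] += 1

        if zero_inflated:
            # gamma block: Bernoulli(1 - z | rho) likelihood + N(0, v) prior
            zf = z.astype(float)

            def bern_ll(eta):
                return float(np.sum((1.0 - zf) * eta - np.logaddexp(0.0, eta)))

            cur_ll = bern_ll(eta_w)
            cur_lp = -0.5 * coef_prec * float(gamma @ gamma)
            prop = gamma + scales["gamma"] * rng.standard_normal(q)
            prop_eta = W @ prop
            prop_ll = bern_ll(prop_eta)
            prop_lp = -0.5 * coef_prec * float(prop @ prop)
            if np.log(rng.random()) < prop_ll + prop_lp - cur_ll - cur_lp:
                gamma, eta_w = prop, prop_eta
                accept["gamma"] += 1
                window["gamma"] += 1

        if hierarchical:
            # city intercepts: scalar Metropolis against Poisson rows of the
            # city + N(0, sigma2) prior; sufficient stats make this cheap
            exp_eta = np.exp(eta_x)
            for c in range(n_city):
                rows = city_rows[c]
                zc = z[rows]
                s1 = float(y[rows][zc].sum())
                s2 = float(exp_eta[rows][zc].sum())
                a = alpha[c]
                prop = a + scales["alpha"] * rng.standard_normal()
                cur = s1 * a - s2 * np.exp(a) - 0.5 * a * a / sigma2
                new = s1 * prop - s2 * np.exp(prop) - 0.5 * prop * prop / sigma2
                if np.log(rng.random()) < new - cur:
                    alpha[c] = prop
                    accept["alpha"] += 1
                    window["alpha"] += 1

            # sigma2: conjugate inverse-gamma full conditional
            shape = priors.sigma2_shape + 0.5 * n_city
            rate = priors.sigma2_rate + 0.5 * float(alpha @ alpha)
            sigma2 = rate / rng.gamma(shape)

        in_burnin = it < config.n_burnin
        if config.adapt and in_burnin and (it + 1) % _ADAPT_WINDOW == 0:
            for block in ("beta", "gamma", "alpha"):
                trials = _ADAPT_WINDOW * (n_city if block == "alpha" else 1)
                if block == "gamma" and not zero_inflated:
                    continue
                if block == "alpha" and not hierarchical:
                    continue
                rate_ = window[block] / trials
                scales[block] *= float(np.exp(rate_ - _TARGET_ACCEPT))
                window[block] = 0
        if not in_burnin:
            if (it - config.n_burnin) % config.thin == 0 and kept < n_kept:
                rho_now = special.expit(eta_w) if zero_inflated else np.zeros(n)
                lam_now = np.exp(eta_x + alpha[ci])
                out["beta"][kept] = beta
                out["gamma"][kept] = gamma
                out["alpha"][kept] = alpha
                out["sigma2"][kept] = sigma2
                out["loglik"][kept] = float(np.sum(zip_log_pmf(y, lam_now, rho_now)))
                out["presence"][kept] = float(np.mean(1.0 - rho_now))
                kept += 1

    rates = {
        b: accept[b] / (config.n_iter * (n_city if b == "alpha" else 1))
        for b in accept
    }
    return out, rates


def sample_posterior(
    data: DesignMatrix,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    zero_inflated: bool = True,
    hierarchical: bool = True,
) -> PosteriorDraws:
    """Draw from the joint posterior of the (ZIP or plain Poisson) model.

    ``zero_inflated=False`` fixes ``rho = 0``: the same regression without
    structural zeros, the reference model for DIC comparison.
    ``hierarchical=False`` drops the city random intercepts (required for
    single-city data, where an intercept and one city effect would be
    confounded).
    """
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    init = ZipParameters(
        beta=np.zeros(data.X.shape[1]),
        gamma=np.zeros(data.W.shape[1]),
        alpha=np.zeros(data.n_cities),
        sigma2=1.0,
    )
    from .zip_model import log_posterior

    if not np.isfinite(log_posterior(init, data, priors)):
        raise RuntimeError(
            "log-posterior not finite at the zero initialization; "
            "check the design matrix for non-finite covariates"
        )

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains, rates = [], []
    for s in seeds:
        draws, rate = _run_chain(data, priors, config, s, zero_inflated, hierarchical)
        chains.append(draws)
        rates.append(rate)

    names = list(data.x_names)
    if zero_inflated:
        names += list(data.w_names)
    if hierarchical:
        names += [f"alpha_{c}" for c in (data.cities or range(data.n_cities))]
        names += ["sigma2"]
    return PosteriorDraws(
        beta=np.stack([c["beta"] for c in chains]),
        gamma=np.stack([c["gamma"] for c in chains]),
        alpha=np.stack([c["alpha"] for c in chains]),
        sigma2=np.stack([c["sigma2"] for c in chains]),
        loglik=np.stack([c["loglik"] for c in chains]),
        presence=np.stack([c["presence"] for c in chains]),
        param_names=names,
        acceptance={
            b: float(np.mean([r[b] for r in rates])) for b in ("beta", "gamma", "alpha")
        },
        zero_inflated=zero_inflated,
        hierarchical=hierarchical,
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chains`` is (n_chains, n_draws). Each chain is split in half, giving
    2m sequences; R-hat is ``sqrt(((n-1)/n W + B/n) / W)``. Degenerate
    (zero-variance) chains report 1.0 by convention.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two chains")
    if chains.shape[1] < 10:
        raise ValueError("need at least 10 draws per chain")
    half = chains.shape[1] // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = split.shape
    means = split.mean(axis=1)
    w = float(split.var(axis=1, ddof=1).mean())
    b = n * float(means.var(ddof=1))
    if w == 0.0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chains: np.ndarray, max_lag: int | None = None) -> float:
    """ESS via initial-positive-sequence autocorrelation summation."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if max_lag is None:
        max_lag = n // 2
    centered = chains - chains.mean(axis=1, keepdims=True)
    var = float(np.mean(centered**2))
    if var == 0:
        return float(m * n)
    acf_sum = 0.0
    for lag in range(1, max_lag):
        r = float(np.mean(centered[:, :-lag] * centered[:, lag:])) / var
        if r < 0.0:
            break
        acf_sum += r
    return m * n / (1.0 + 2.0 * acf_sum)


def mc_standard_error(chains: np.ndarray) -> float:
    """Monte-Carlo standard error of the posterior mean (ESS-based)."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    return float(chains.std(ddof=1)) / np.sqrt(effective_sample_size(chains))


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, 95% credible interval, R-hat and CI-excludes-zero flag.

    Quantiles use linear interpolation of order statistics. A final
    "Presence" row gives the posterior mean suitability probability
    (mean over draws and rows of ``1 - rho_is``), the model-based analogue
    of the proportion of occupied sites.
    """
    arr = draws.stacked()
    rows = []
    for j, name in enumerate(draws.param_names):
        param = arr[:, :, j]
        flat = param.ravel()
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "q2.5": float(lo),
                "q97.5": float(hi),
                "rhat": gelman_rubin(param) if draws.n_chains > 1 else np.nan,
                "excludes_zero": bool(lo > 0 or hi < 0),
            }
        )
    if draws.zero_inflated:
        pres = draws.presence.ravel()
        lo, hi = np.percentile(pres, [2.5, 97.5])
        rows.append(
            {
                "parameter": "Presence",
                "mean": float(pres.mean()),
                "q2.5": float(lo),
                "q97.5": float(hi),
                "rhat": gelman_rubin(draws.presence) if draws.n_chains > 1 else np.nan,
                "excludes_zero": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


def fit_model(
    data: DesignMatrix,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    zero_inflated: bool = True,
    hierarchical: bool = True,
) -> ModelFit:
    """Sample the posterior and attach the summary table."""
    priors = priors or PriorSpec()
    config = config or SamplerConfig()
    draws = sample_posterior(data, priors, config, zero_inflated, hierarchical)
    return ModelFit(
        data=data,
        draws=draws,
        summary=summarize_posterior(draws),
        config=config,
        priors=priors,
    )
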