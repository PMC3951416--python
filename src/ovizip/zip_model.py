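"""Zero-inflated Poisson (ZIP) regression with latent site suitability.

The response is the rounded mean larval count of one species at one
site-season (``Y_is``). A site-season is either *unsuitable* — with
probability ``rho_is`` it yields a structural zero — or suitable, in which
case the count is Poisson with mean ``lambda_is``. The total probability of
observing a zero is therefore ``delta_is = rho + (1 - rho) * exp(-lambda)``.

Suitability is modelled on the logit scale as a function of season
(``logit(rho_is) = W @ gamma``), and abundance on the log scale as a linear
function of covariates plus a city-level random intercept
(``log(lambda_is) = X @ beta + alpha[city]``, ``alpha_c ~ N(0, sigma2)``).
Priors are vague: N(0, 1000) on every regression coefficient and an
inverse-gamma(0.01, 0.01) (shape/rate convention) on the city-effect
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

#: the three focal species; "OTHER" is read from trap tables but never modelled
SPECIES = ("ALB", "AEG", "CQ")

#: land-cover covariates of the habitat-segregation model, in table order
LANDCOVER_CLASSES = ("wetland", "high_intensity_developed", "open_space_developed")


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters for the ZIP regression.

    coef_variance
        Variance of the mean-zero Gaussian prior shared by every element of
        ``beta`` and ``gamma``.
    sigma2_shape, sigma2_rate
        Shape and rate of the inverse-gamma prior on the city-effect
        variance (BUGS-style shape/rate parameterization).
    """

    coef_variance: float = 1000.0
    sigma2_shape: float = 0.01
    sigma2_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.coef_variance <= 0 or self.sigma2_shape <= 0 or self.sigma2_rate <= 0:
            raise ValueError("prior hyperparameters must be strictly positive")


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Response and covariates for one species' regression.

    Rows are site-seasons. ``X`` always starts with an intercept column and
    codes season as month = 0 (early, June) / 1 (late, September). ``W`` is
    the zero-inflation design (intercept, month). ``city_index`` maps each
    row to an integer city code.
    """

    y: np.ndarray
    X: np.ndarray
    W: np.ndarray
    city_index: np.ndarray
    x_names: list[str]
    w_names: list[str]
    row_meta: pd.DataFrame
    species: str = ""
    cities: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (self.X.shape[0] == self.W.shape[0] == len(self.city_index) == n):
            raise ValueError("y, X, W and city_index must have equal row counts")
        if self.X.shape[1] != len(self.x_names) or self.W.shape[1] != len(self.w_names):
            raise ValueError("column-name lists do not match matrix widths")

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_cities(self) -> int:
        return int(self.city_index.max()) + 1 if len(self.city_index) else 0

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a single auditable table (one row per observation)."""
        out = self.row_meta.copy()
        out["y"] = self.y
        out["city_index"] = self.city_index
        for j, name in enumerate(self.x_names):
            out[f"X:{name}"] = self.X[:, j]
        for j, name in enumerate(self.w_names):
            out[f"W:{name}"] = self.W[:, j]
        return out


def build_design_matrix(
    records: pd.DataFrame,
    species: str,
    variant: str = "A",
    covariates: pd.DataFrame | None = None,
    scale: int = 200,
) -> DesignMatrix:
    """Assemble the design matrix for one species under one model variant.

    Parameters
    ----------
    records
        Site-season table as returned by
        :func:`ovizip.study_design.records_to_frame`: one row per site and
        season with columns ``site_id, city_id, site_class, season, month``,
        ``y_<SP>`` and ``present_<SP>`` per species.
    species
        Focal species code ("ALB", "AEG" or "CQ").
    variant
        "A" — seasonality and co-occurrence: intercept, month, and presence
        indicators of the two other species.
        "B" — habitat segregation: intercept plus, for cemetery and each
        land-cover proportion, separate early- and late-season columns
        (``x * (1 - month)`` and ``x * month``); no month main effect.
    covariates
        Standardized land-cover table indexed by site_id with columns
        ``<class>_<scale>`` (required for variant B).
    scale
        Buffer radius in metres selecting the covariate columns (50 or 200).
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    records = records.reset_index(drop=True)
    month = records["month"].to_numpy(dtype=float)
    n = len(records)
    intercept = np.ones(n)

    if variant == "A":
        others = [s for s in SPECIES if s != species]
        cols = [intercept, month] + [
            records[f"present_{s}"].to_numpy(dtype=float) for s in others
        ]
        x_names = ["intercept", "month"] + [f"{s}_present" for s in others]
    elif variant == "B":
        if covariates is None:
            raise ValueError("variant B requires a land-cover covariate table")
        cemetery = (records["site_class"] == "cemetery").to_numpy(dtype=float)
        missing = set(records["site_id"]) - set(covariates.index)
        if missing:
            raise KeyError(f"sites missing from covariate table: {sorted(missing)}")
        cols, x_names = [intercept], ["intercept"]
        base = {"cemetery": cemetery}
        for cls in LANDCOVER_CLASSES:
            col = f"{cls}_{scale}"
            if col not in covariates.columns:
                raise KeyError(f"covariate table lacks column {col!r}")
            base[cls] = covariates[col].reindex(records["site_id"]).to_numpy(dtype=float)
        for name, x in base.items():
            cols.append(x * (1.0 - month))
            x_names.append(f"{name}_early")
            cols.append(x * month)
            x_names.append(f"{name}_late")
    else:
        raise ValueError(f"unknown model variant {variant!r}; expected 'A' or 'B'")

    cities = sorted(records["city_id"].unique())
    city_index = records["city_id"].map({c: i for i, c in enumerate(cities)})
    return DesignMatrix(
        y=records[f"y_{species}"].to_numpy(dtype=np.int64),
        X=np.column_stack(cols),
        W=np.column_stack([intercept, month]),
        city_index=city_index.to_numpy(dtype=np.int64),
        x_names=x_names,
        w_names=["zi_intercept", "zi_month"],
        row_meta=records[["site_id", "city_id", "site_class", "season"]].copy(),
        species=species,
        cities=list(cities),
    )


# ---------------------------------------------------------------------------
# parameters and likelihood
# ---------------------------------------------------------------------------

@dataclass
class ZipParameters:
    """One point in parameter space for the hierarchical ZIP regression."""

    beta: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    sigma2: float

    def copy(self) -> "ZipParameters":
        return replace(
            self,
            beta=self.beta.copy(),
            gamma=self.gamma.copy(),
            alpha=self.alpha.copy(),
        )

    def lam(self, data: DesignMatrix) -> np.ndarray:
        """Poisson mean per row, ``exp(X @ beta + alpha[city])``."""
        return np.exp(data.X @ self.beta + self.alpha[data.city_index])

    def rho(self, data: DesignMatrix) -> np.ndarray:
        """Structural-zero (unsuitability) probability per row."""
        return special.expit(data.W @ self.gamma)

    def delta(self, data: DesignMatrix) -> np.ndarray:
        """Total zero probability per row, ``rho + (1 - rho) e^{-lambda}``."""
        rho = self.rho(data)
        return rho + (1.0 - rho) * np.exp(-self.lam(data))


def zip_log_pmf(y, lam, rho):
    """Log-pmf of the ZIP distribution, elementwise and numerically stable.

    ``y = 0``: ``log(rho + (1 - rho) e^{-lambda})``;
    ``y > 0``: ``log(1 - rho) + y log(lambda) - lambda - log(y!)``.
    ``rho = 1`` with positive ``y`` yields ``-inf`` rather than an error.
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore"):
        log_rho = np.log(rho)
        log_1mrho = np.log1p(-rho)
        log_lam = np.log(lam)
    zero_case = np.logaddexp(log_rho, log_1mrho - lam)
    pos_case = log_1mrho + y * log_lam - lam - special.gammaln(y + 1)
    out = np.where(y == 0, zero_case, pos_case)
    return out if out.ndim else float(out)


def zip_moments(lam, rho):
    """Closed-form (mean, variance, overdispersion) of ZIP(lam, rho).

    mean = (1 - rho) * lam; variance = mean * (1 + rho * lam);
    overdispersion index Var/E = 1 + rho * lam.
    """
    lam = np.asarray(lam, dtype=float)
    rho = np.asarray(rho, dtype=float)
    mean = (1.0 - rho) * lam
    od = 1.0 + rho * lam
    return mean, mean * od, od


def zip_rvs(lam, rho, rng: np.random.Generator, size=None):
    """Draw ZIP variates: structural zero w.p. rho, else Poisson(lam)."""
    if size is None:
        shape = np.broadcast_shapes(np.shape(lam), np.shape(rho))
    elif np.isscalar(size):
        shape = (int(size),)
    else:
        shape = tuple(size)
    lam = np.broadcast_to(np.asarray(lam, dtype=float), shape)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), shape)
    suitable = rng.random(shape) >= rho
    return np.where(suitable, rng.poisson(lam), 0)


def log_likelihood(params: ZipParameters, data: DesignMatrix) -> float:
    """Marginal ZIP log-likelihood (latent suitability integrated out)."""
    return float(np.sum(zip_log_pmf(data.y, params.lam(data), params.rho(data))))


def log_posterior(params: ZipParameters, data: DesignMatrix, priors: PriorSpec) -> float:
    """Joint log-posterior density (unnormalized); -inf outside support."""
    p, q = data.X.shape[1], data.W.shape[1]
    if len(params.beta) != p or len(params.gamma) != q:
        raise ValueError(
            f"parameter dimensions ({len(params.beta)}, {len(params.gamma)}) "
            f"do not match design ({p}, {q})"
        )
    if len(params.alpha) != data.n_cities:
        raise ValueError("one city effect required per city in the design")
    if not np.isfinite(params.sigma2) or params.sigma2 <= 0:
        return -np.inf
    ll = log_likelihood(params, data)
    sd = np.sqrt(priors.coef_variance)
    lp = float(
        np.sum(stats.norm.logpdf(params.beta, 0.0, sd))
        + np.sum(stats.norm.logpdf(params.gamma, 0.0, sd))
        + np.sum(stats.norm.logpdf(params.alpha, 0.0, np.sqrt(params.sigma2)))
        + stats.invgamma.logpdf(
            params.sigma2, priors.sigma2_shape, scale=priors.sigma2_rate
        )
    )
    return ll + lp
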