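# Methods

## The model

The response unit is a site-season: the per-species mean larval count over
the (up to three) valid ovitraps at a site in one sampling round, rounded
to the nearest integer. Counts like these are dominated by zeros, and a
plain Poisson regression badly understates both the zero fraction and the
variance. The package therefore fits a zero-inflated Poisson (ZIP) mixture
with a latent site-suitability indicator:

    Y_is ~ 0                 with probability rho_is        (unsuitable)
    Y_is ~ Poisson(lambda_is) with probability 1 - rho_is   (suitable)

    logit(rho_is)  = gamma_0 + gamma_1 * month
    log(lambda_is) = x_is' beta + alpha_c(i),   alpha_c ~ N(0, sigma2)

`month` codes the sampling round (early rainy season, June = 0; late,
September = 1). The city random intercept `alpha_c` absorbs shared
within-city variation in abundance beyond what the covariates explain; one
`sigma2` is estimated per species fit. Note the zero-inflation convention:
`rho` is the probability of *unsuitability*, so a negative `gamma_1` means
structural zeros are less likely late in the season.

Two covariate sets are fit separately, each per species:

* **Variant A (seasonality / co-occurrence)** — intercept, month, and
  binary presence indicators of the two other focal species at the same
  site-season. A species' own presence is never a covariate.
* **Variant B (habitat segregation)** — intercept plus, for cemetery
  status and each land-cover proportion (wetland, high-intensity
  developed, open-space developed), separate early- and late-season
  coefficients (`x * (1 - month)` and `x * month`). There is no separate
  month main effect in the abundance part; seasonality enters only through
  the per-season coefficient pairs and the zero-inflation season term.

Priors are deliberately vague: N(0, 1000) on every regression coefficient
(both `beta` and `gamma`) and inverse-gamma(0.01, 0.01) on `sigma2`, in the
shape/rate convention. All coefficients are interpretable on the log scale;
`(exp(b) - 1) * 100` converts an effect to a percent change in relative
abundance.

## Data rules

Disturbed traps carry no information and are dropped before any analysis.
Dry (but intact) traps are excluded from the site mean's denominator — a
dry cup cannot hold larvae, and counting it as a zero would conflate
drying with absence — but they do not remove the site; only a site-season
whose remaining traps are all dry is removed. The site mean is rounded
half away from zero (the rounding rule is isolated in one function,
`round_half_away`; numpy's banker's rounding would map 2.5 to 2).
Presence for the co-occurrence covariates and the occupancy tables is
defined at the site-season level: any valid trap with a positive count.
The rarely collected species pooled as "other" are read and retained but
never modelled.

Occupancy is cross-tabulated into the eight exclusive categories
(each single species, each pair, all three, none). Pairwise co-occurrence
statistics are *exclusive*: a site where all three species occur counts in
the triple category, not in any pair. Trap-occupancy proportions use an
externally supplied denominator (the number of undisturbed traps), since
empty traps may be represented implicitly. The shipped published
cross-tab's late-season trap category counts sum to 363 while the printed
stratum total is 347; the table keeps the printed total as its denominator
(which is what the printed proportions use), and only the *site* partition
is enforced as an invariant.

## Land cover

Covariates come from categorical rasters (30 m pixels by default) by
tabulating class proportions in circular buffers of 50 m and 200 m around
each site. Pixel membership is center-in-circle, matching plain pixel
tabulation practice; no area weighting and no projection handling.
Proportions are screened for collinearity — a class whose Pearson
correlation is significant (two-sided p < 0.05 by default) with every
other retained class is dropped, the way low-intensity developed cover
behaves in dense urban rasters — then z-scored across sites. Proportions
are *not* renormalized after a class is dropped; renormalizing would
change the remaining coefficients' scale, and the raw-proportion scale is
the interpretable one. Cemetery status is an input flag, never inferred
from land cover (cemeteries fall inside the open-space class).

## Inference

The sampler is Metropolis-within-Gibbs with data augmentation. The latent
indicator `z` (suitability) is drawn exactly from its Bernoulli
conditional — positive counts force `z = 1`; at zeros
`P(z = 1) = (1 - rho) e^-lambda / (rho + (1 - rho) e^-lambda)`. Given
`z`, `beta` is updated as one random-walk Metropolis block against the
Poisson likelihood of the suitable rows, `gamma` as one block against the
Bernoulli likelihood of `1 - z`, each `alpha_c` by scalar Metropolis
(cheap via per-city sufficient statistics), and `sigma2` exactly from its
conjugate inverse-gamma conditional. Deviance and DIC use the *marginal*
likelihood with `z` integrated out, so ZIP and Poisson deviances are
directly comparable; the conditional-on-`z` deviance would make the
effective parameter counts incommensurable.

Numerical choices:

* Initialization: all coefficients 0, `sigma2 = 1`, `z = 1` exactly at the
  positive counts — deterministic and inside the support. A non-finite
  log-posterior at initialization raises immediately.
* Proposal scales adapt every 50 iterations during burn-in only (scale
  multiplied by `exp(rate - 0.3)`), so post-burn-in kernels are fixed and
  detailed balance holds for every retained draw.
* Chains are seeded from independent `SeedSequence` substreams of one
  master seed: runs are bitwise reproducible and chain k's draws do not
  change when more chains are added.
* Credible intervals are empirical 2.5/97.5 percentiles with linear
  interpolation of order statistics; this affects only the last digit.
* Convergence is monitored with the split-chain Gelman-Rubin statistic
  (constant chains report 1.0 by convention); the per-fit summary also
  reports a "Presence" row, the posterior mean of `1 - rho_is` over rows
  and draws — the model-based analogue of the proportion of occupied
  sites.
* The production default is 3 chains x 20,000 iterations (5,000 burn-in,
  thinning 5). The test suite and the acceptance script use 2-3 chains of
  3,000-6,000 iterations: at a few hundred site-seasons and at most nine
  coefficients the posterior is well explored at that length (focal-
  parameter R-hat below 1.1 and acceptance rates near 0.3), and simulation
  studies repeat the fit twenty times. The intercept and the city
  intercepts are weakly identified against one another (only their sum
  enters `log lambda`), so their individual R-hat converges more slowly
  than every other parameter; harnesses gate on the focal parameter.

With a single city the intercept and city effect are exactly confounded,
so the sampler accepts `hierarchical=False` (no city effects), which is
also what the one-parameter oracle fixture uses.

## Model comparison

The Poisson reference is the same regression with `rho` fixed at zero —
same design, priors and hierarchy. Comparison reports, per species: the
observed zero fraction and overdispersion index `OD.i = Var(y)/E(y)`
(sample variance, n-1 denominator; immaterial at these n) next to their
posterior-predictive means under each model, and
`delta_DIC = DIC(Poisson) - DIC(ZIP)`, with a preference declared only
beyond 5 units. Posterior-predictive quantities simulate one full
replicate response vector per retained draw (subsampled to 500 draws).

## The synthetic generator

`ScenarioConfig` defaults reproduce the real design: 3 cities with
(34, 34, 32) urban sites and (10, 5, 4) cemeteries (100 + 19 sites), 3
traps per site, 2 seasons. Land cover is a smoothed categorical field
(Gaussian low-pass noise per class, argmax of class scores) — it exercises
the full buffer-extraction contract but has no real-world spatial
semantics. Counts follow the model exactly: suitability is flipped per
species and site-season, and, when suitable, each trap draws Poisson
around the shared site mean, so the mean-then-round aggregation path is
exercised end to end. Trap losses are applied after generation and only
censor (dry probability increases with surrounding high-intensity cover
via a logit link, base rate 0.08, slope 1.5; disturbance is independent at
0.03, close to the 22-of-714 loss rate of the real survey).

Default true parameters mirror the published effect magnitudes: abundance
intercepts/month effects (0.99, 1.42), (1.48, 0.82), (4.27, -0.68) for
ALB/AEG/CQ, seasonal suitability slopes -0.658/+0.862/+1.389 on
logit(rho) (the sign flip relative to the published values reflects the
rho-as-unsuitability convention), zero-inflation intercepts chosen so mean
suitability tracks the observed occupancy levels (0.22/0.47/0.42), and
`sigma2 = 0.25` for the city effects (a realistic within-region spread;
not a published value).

A `site_level=True` mode draws the response directly at the site-season
unit (one ZIP draw, no traps). The parameter-recovery harness uses this
mode: recovery and coverage statements are about a correctly specified
model, whereas trap-level generation followed by mean-then-round
aggregation deliberately induces the same mild misspecification the real
analysis accepts (the rounded mean of three Poisson draws is
underdispersed relative to Poisson). The trap-level path is validated
separately (moment checks, end-to-end pipeline runs).

What passing synthetic tests do **not** show: robustness to real-data
features the generator omits — spatial autocorrelation between nearby
sites, overdispersion beyond the structural zeros (e.g. clustered
oviposition within a trap), season-by-covariate confounding, and
measurement error in species identification.

## Problem sizes

The recovery experiment runs 20 replicates of 200 site-seasons (100 sites,
2 seasons, 3 cities) with the true month effect 1.42 — the published ALB
magnitude — and requires >= 80% CI coverage and >= 90% sign recovery among
converged replicates (focal-parameter R-hat <= 1.1; non-converged
replicates are excluded and counted). The model-selection experiment uses
the same design with a constant structural-zero probability of 0.4 and
requires the ZIP fit to beat the Poisson fit by more than 5 DIC units.
The moment check uses 100,000 ZIP draws against the closed forms, with
exact sampling standard errors computed from the pmf. The oracle check
compares the MCMC posterior-mean Poisson rate on a 30-observation
intercept-only fixture with dense grid integration (120,001 nodes over
beta_0 in [-2, 4]) within 3 ESS-based Monte-Carlo standard errors.

## Known limitations

* The original study's posterior tables cannot be reproduced numerically:
  the raw field counts were never deposited. Everything derivable from the
  published cross-tabulations and reported coefficients is reproduced
  exactly; the model-fitting machinery is validated by simulation instead.
* No negative-binomial or hurdle alternatives, no WAIC/LOO, no spatial
  autocorrelation terms, no geographic projections — out of scope by
  design.
* Random-walk Metropolis mixes slowly for the weakly identified
  intercept/city-effect pair; hierarchical centering or a joint update
  would help if city effects themselves were ever the quantity of
  interest.
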