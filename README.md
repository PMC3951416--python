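# ovizip

Hierarchical zero-inflated Poisson analysis of container-mosquito
oviposition-trap surveys.

Standardized ovitraps are the workhorse of surveillance for
container-breeding disease vectors (*Aedes albopictus*, *Aedes aegypti*,
*Culex quinquefasciatus*). Trap-level larval counts from urban surveys are
dominated by zeros — some because a suitable site happened to catch
nothing, some because the site is genuinely unsuitable — and a plain
Poisson regression misrepresents both the zero fraction and the variance.
`ovizip` implements the full analysis pipeline for such surveys: the data
exclusion and aggregation rules of a replicated multi-city ovitrap design,
occupancy and co-occurrence cross-tabulation, land-cover buffer
covariates, and a Bayesian hierarchical ZIP regression with latent site
suitability, fit by a purpose-built Metropolis-within-Gibbs sampler.

## The model

For species *s* at site *i* (one observation per site-season),

```
Y_is = 0                  with probability rho_is        (site unsuitable)
Y_is ~ Poisson(lambda_is) with probability 1 - rho_is    (site suitable)

logit(rho_is)  = gamma_0 + gamma_1 * month
log(lambda_is) = x_is' beta + alpha_c(i),    alpha_c ~ N(0, sigma2)
```

with month coded early (June) = 0 / late (September) = 1, a city random
intercept `alpha_c`, N(0, 1000) priors on all coefficients and an
inverse-gamma(0.01, 0.01) prior on `sigma2`. Covariates are either
seasonality plus competitor presence (variant A) or cemetery status and
land-cover proportions with separate early/late coefficients (variant B,
at a 50 m or 200 m buffer scale). The fitted ZIP model is compared against
the matching Poisson regression (`rho = 0`) by DIC (differences > 5 are
decisive), zero fraction and the overdispersion index `Var(y)/E(y)`.
See `docs/methods.md` for the complete account.

## Worked example

Simulate a survey with the default design — 3 cities, 100 urban + 19
cemetery sites, 3 traps per site, 2 seasons, true parameters mirroring the
published effect magnitudes — and fit the seasonal/co-occurrence model for
*A. aegypti*:

```python
import numpy as np
from ovizip import (ScenarioConfig, simulate_study, build_design_matrix,
                    fit_model, SamplerConfig, compare_models)

study = simulate_study(ScenarioConfig(seed=42))
data = build_design_matrix(study.records_frame(), "AEG", variant="A")
sc = SamplerConfig(n_chains=2, n_iter=6000, n_burnin=2000, thin=2, seed=1)
fit = fit_model(data, config=sc)
print(fit.summary.round(3).to_string(index=False))
```

```
   parameter   mean   q2.5  q97.5  rhat  excludes_zero
   intercept  0.951  0.054  1.954 1.604           True
       month  0.787  0.648  0.922 1.014           True
 ALB_present  0.062 -0.077  0.195 1.003          False
  CQ_present -0.021 -0.181  0.135 1.015          False
zi_intercept -0.427 -0.818 -0.074 1.001           True
    zi_month  0.917  0.432  1.421 1.002           True
 alpha_city1  0.572 -0.373  1.437 1.611          False
 alpha_city2  1.147  0.158  2.030 1.604           True
 alpha_city3  0.873 -0.111  1.740 1.607          False
      sigma2  2.898  0.040 17.187 1.017           True
    Presence  0.492  0.431  0.554 1.000           True
```

The month CI (0.65, 0.92) covers the generative truth 0.82, the
zero-inflation season effect (0.43, 1.42) covers its truth 0.862
(structural zeros more likely late for this species), and "Presence" —
the posterior mean suitability probability — recovers the generative
occupancy level 0.47. The intercept and the city effects are individually
weakly identified (only their sum enters `log lambda`), which their high
R-hat flags; the focal coefficients mix well. A percent-change reading of
a coefficient: `coef_to_percent_change(0.787)` = +119.7%, the increase in
relative abundance from the early to the late rainy season.

Comparing against the Poisson reference on the same data:

```python
pois = fit_model(data, config=sc, zero_inflated=False)
print(compare_models(pois, fit, np.random.default_rng(0)))
```

```
species                AEG
zeros_observed       0.508
zeros_poisson        0.024
zeros_zip            0.513
od_observed          6.996
od_poisson           1.425
od_zip               7.893
dic_poisson       2136.775
dic_zip            832.408
delta_dic         1304.368
preferred              ZIP
```

Half the site-season responses are zero; the Poisson fit predicts 2%
zeros while the ZIP fit reproduces the observed fraction and wins by
~1300 DIC units.

The same pipeline is available from the shell:

```sh
ovizip simulate --seed 7 --outdir data/
ovizip fit --config analysis.yaml --seed 7 --outdir out/ --model A
ovizip compare --outdir out/
ovizip report --outdir out/
```

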