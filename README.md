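# bmis

Bayesian estimation of **sensitivity and specificity of maternal-death
reporting** in civil registration and vital statistics (CRVS) systems, for
many countries and years, from sparse and heterogeneous specialized-study
data — and the CRVS **adjustment factors** that correct reported maternal
mortality for misclassification.

## Who this is for

CRVS systems record deaths of women of reproductive age with an ICD-coded
cause. Maternal deaths are frequently misclassified: some true maternal
deaths are coded non-maternal (false negatives) and some non-maternal
deaths are coded maternal (false positives). Specialized studies — reviews
that confirm the true maternal status of all CRVS-reported deaths in a
country-period — measure this error, but exist only for a limited set of
country-periods, and most report only aggregated, *overlapping* totals:
the confirmed maternal count `z_true = T+ + F−` and the CRVS-coded count
`z_mat = T+ + F+`. This package is for analysts who need misclassification
estimates for *every* country-year, with honest uncertainty, from exactly
that kind of data.

## The model

For a study covering country *c* with midyear *t*, the four cell counts of
the (true cause × coded cause) table are multinomial within the CRVS
envelope `z_crvs`:

    z = (z_T+, z_F+, z_F−, z_T−) ~ Multinomial(z_crvs, γ)

with cell probabilities parameterized by sensitivity λ⁺, specificity λ⁻ and
the true maternal proportion γ_true:

    γ_T+ = λ⁺ γ_true            γ_F− = (1 − λ⁺) γ_true
    γ_T− = λ⁻ (1 − γ_true)      γ_F+ = (1 − λ⁻)(1 − γ_true)

Studies reporting all four cells use this multinomial directly; studies
reporting `(F−, T−, mat)` use the multinomial with the `(T+, F+)` cells
merged; studies reporting only the overlapping totals `(z_true, z_mat)`
use an **exact likelihood** that enumerates every latent table consistent
with the two marginals (a one-parameter family indexed by the T+ count)
and sums their multinomial probabilities.

Probit-transformed sensitivity and specificity follow a **bivariate
hierarchical random walk**: each country's series is its mean level plus a
linear combination of first-order differences, `η_{1:T} = η̄ + D ξ` with
`D = W'(WW')⁻¹` the pseudo-inverse of the differencing matrix `W`; country
mean levels are bivariate normal around global levels (SDs σ⁺, σ⁻,
correlation ρ) and innovations are bivariate normal (SDs δ⁺, δ⁻,
correlation φ). Posterior sampling is by adaptive Metropolis-within-Gibbs.

The CRVS adjustment factor — the ratio of true to reported proportion
maternal — follows per posterior draw:

    Ω = γ_true / ( λ⁺ γ_true + (1 − λ⁻)(1 − γ_true) )

which equals 1/λ⁺ when specificity is one and decreases with decreasing
true PM otherwise.

## Worked example

```python
import numpy as np
from bmis import BMisModel, FitConfig, WorldConfig, generate_world

world = generate_world(WorldConfig(n_countries=15, seed=114))   # synthetic CRVS + studies
model = BMisModel(world.dataset)
res = model.fit(FitConfig.desk(seed=1))
print(res.summary().round(3))
```

```
                      q10    q50    q90
parameter
lambda_global_sens  0.558  0.645  0.722
lambda_global_spec  0.999  0.999  1.000
rho                -0.753 -0.164  0.526
sigma_sens          0.461  0.607  0.817
sigma_spec          0.018  0.102  0.218
phi                -0.460 -0.038  0.502
delta_sens          0.072  0.103  0.145
delta_spec          0.076  0.109  0.149
```

The rows are the eight hyperparameters — global sensitivity and
specificity (probability scale), the between-country correlation and SDs
of the mean probit levels, and the innovation correlation and SDs — with
posterior median and 80% credible bounds. This world was generated with
global sensitivity 0.593 and specificity 0.9995; both lie inside their
intervals. Country-year estimates and adjustment factors:

```python
res.sens("C03", 2010)            # posterior draws of sensitivity
res.summary_series()             # long table of 10/50/90% quantiles
import pandas as pd
pm = pd.DataFrame({"country": ["C03"], "year": [2010], "true_pm": [0.01]})
res.adjustment_samples(pm).frame # Omega with 80% interval
```

A command-line interface mirrors the library:
`bmis simulate | fit | adjust | validate` (see `bmis --help`).

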