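# Methods

## Problem and model

The package estimates, for every country-year on a configurable grid
(default 1985–2017), the sensitivity λ⁺ (probability a true maternal death
inside the CRVS envelope is coded maternal) and specificity λ⁻
(probability a non-maternal death is coded non-maternal) of maternal-death
reporting, from specialized-study records of heterogeneous detail, and
derives CRVS adjustment factors Ω = true PM / reported PM per posterior
draw.

### Observation model

Each study *i* covers country c[i] over years [t1, t2] with midyear t[i]
(floor of the arithmetic mean; the rounding rule is a package convention).
Its counts are modelled as one multinomial draw of the envelope `z_crvs`
over the four classification cells, with cell probabilities built from
(λ⁺, λ⁻, γ_true) evaluated **at the midyear**. Three reporting patterns
are supported, inferred purely from which columns are populated:

* **full breakdown** — all four cells: plain multinomial likelihood;
* **partial (F− only)** — counts (F−, T−, mat): multinomial with the
  T+ and F+ categories merged (an exact aggregation identity, tested);
* **overlapping totals** — only `z_true = T+ + F−` and `z_mat = T+ + F+`:
  the likelihood sums the multinomial pmf over every latent table
  consistent with the two marginals. Because two marginal constraints
  leave one degree of freedom, tables are enumerated by the T+ count alone
  (`S = min(z_mat, z_true) − max(0, z_mat + z_true − z_crvs) + 1` tables).
  All sums are done in log space with log-sum-exp; multinomial
  coefficients use log-gamma, so envelopes of 10⁵–10⁶ are safe.

For inference, tables whose T− count is at or below the 0.025 quantile of
Binomial(z_crvs − z_true, 0.97) are pruned (strict inequality keeps a
table). This is a computational device that removes negligible-probability
tables; it is on by default for fitting and off wherever exactness is
asserted. The "0.97 / 2.5th percentile" pairing is implemented exactly as
the rule is usually stated and kept as a named constant
(`bmis.likelihood.EXCLUSION_P`); for realistic data (z_mat ≪ 3% of the
envelope) it prunes little or nothing, so the likelihood used in practice
is effectively exact.

Each study carries its own true-proportion parameter γ_true,i with a
uniform(0.0001, 1) prior, attached at the study midyear. Country-years
without studies carry no γ_true parameter: the likelihood touches γ_true
only through study counts, and the true PM elsewhere is an external input
(estimated by a separate all-cause model) that this package deliberately
does not reproduce.

### Process model

Probit-transformed sensitivity and specificity follow a bivariate
hierarchical random walk. Writing η = Φ⁻¹(λ), each country's length-T
series is decomposed as mean level plus first differences,
`η_{1:T} = η̄ + D ξ`, `D = W'(WW')⁻¹`, which makes the (mean, differences)
parameterization exactly invertible (identities `W D = I` and
`mean(v) + D W v = v` are tested for T = 2…50 at 1e−10). Country means are
bivariate normal around global levels with SDs (σ⁺, σ⁻) and correlation ρ;
paired innovations are zero-mean bivariate normal with SDs (δ⁺, δ⁻) and
correlation φ. Priors: uniform(0,1) on the two global probabilities
(sampled directly on the probability scale, sidestepping any Jacobian
ambiguity between the two transform conventions), uniform(−1,1) on ρ and
φ, standard half-normal on the four SDs.

The probit convention is: η unconstrained real, λ = Φ(η). Countries
contribute the full 1…T latent series regardless of data coverage, which
is what enables extrapolation to country-years without studies.

## Inference

Sampling is by an adaptive Metropolis-within-Gibbs scheme written for this
model (`bmis/_mcmc.py`):

* per-study γ_true: logit-scale random walks, all studies in parallel;
* country mean levels and each time-slot's innovation pair: joint 2-d
  random walks proposed for all countries simultaneously (countries are
  conditionally independent given the hyperparameters);
* hyperparameters: scalar Metropolis steps on transformed scales (probit
  for global levels, log for SDs) — given the latents these touch only
  bivariate-normal prior terms;
* three families of interweaved joint moves that break the hierarchical
  funnels: translating a global level together with every country mean,
  and rescaling σ or δ together with the latent vector they govern. The
  standardized prior quadratics are invariant under these maps, so the
  acceptance ratio reduces to the likelihood change plus a net `+log a`
  (normalization vs. Jacobian) and the half-normal term. Without these
  moves the global-specificity and variance parameters mix an order of
  magnitude slower.

Proposal scales adapt per component during burn-in (Robbins–Monro toward
0.44 acceptance for scalar updates, 0.30 for 2-d blocks, batch size 50,
gain 1/√batch capped at 0.5) and are frozen afterwards. The per-study
likelihood is evaluated by a single-pass compiled kernel (numba) with an
identical vectorized numpy fallback; both are cross-checked against the
reference per-study implementation at 1e−9.

The production schedule matches the one used for the published UN-MMEIG estimates: 10 chains × 40 000
iterations, 10 000 burn-in, thin 20 (15 000 retained draws).
`FitConfig.desk()` (4 × 5 000, burn-in 2 000, thin 6) is the documented
schedule for interactive work; tests and the acceptance script use still
shorter schedules (2–3 chains × 1 500–2 200) chosen as the package's own
trade-off so the full replicate batteries run on one CPU.

Convergence is monitored on the eight hyperparameters plus each country's
two mean levels: split-R̂ (implemented directly, with the zero-variance
case defined as exactly 1) and bulk effective sample size (arviz). A fit
with any monitored split-R̂ above 1.1 is flagged with a warning and
`converged=False`, never silently returned. Summaries report 10/50/90%
quantiles (80% credible bounds) using numpy's default linear-interpolation
quantile definition.

## Adjustment factors

`adjustment_factor(se, sp, g) = g / (se·g + (1−sp)(1−g))`, evaluated per
posterior draw for full uncertainty propagation; the true PM g is supplied
externally. Closed forms used as tests: Ω = 1/se exactly when sp = 1 (any
g), Ω strictly increasing in g when sp < 1 (∂Ω/∂g ∝ (1−sp) > 0).

The pre-2019 baseline (`unmmeig2015_series`) anchors Ω̂ = z_true/z_mat at
study midyears (both PMs share the envelope, so the ratio simplifies),
interpolates linearly between midyears, holds the latest value constant
forward, and ramps linearly (on the natural scale — the simplest reading
of "linearly") from the earliest *observed midyear* back to the global
value 1.5 over 5 years, constant before. Multiple studies at one midyear
are averaged; multi-year studies anchor at their midyear. Uncertainty is
the fixed expert-based log-normal SD of 0.25. Studies without a confirmed
maternal total (partial breakdowns) or with z_mat = 0 cannot provide a
ratio and are skipped with a warning.

## Validation harness

Two exercises: leave-20%-out at random (repeated) and leave-each-country's
latest study out (ties on midyear break by later end year, then study id).
For a left-out study, the predicted CRVS-reported PM per posterior draw is
`se·p_true + (1−sp)(1−p_true)` with `p_true = z_true/z_crvs`, and by
default a binomial count is redrawn on the envelope so that
observation-level 80% intervals include stochastic uncertainty
(`include_binomial=False` gives parameter-uncertainty-only intervals; the
default matches how observation-level intervals are usually displayed,
and small-count observations would otherwise be incomparable). The
baseline predicts `p_true / Ω` with Ω log-normal around the interpolated
point estimate (global 1.5 where a country has no usable training study).
Both methods always consume identical splits (hash-checked).

One property of this construction is worth knowing: the redrawn binomial
is independent of the observed counts, while the observed `z_mat` shares
its T+ component with the `z_true` being conditioned on. In the regime
where count noise dominates (small envelopes or very tight posteriors),
the recipe's intervals are therefore structurally conservative — a
known-parameter simulation shows ~94% coverage of nominal-80% intervals —
whereas in the parameter-uncertainty-dominated regime of large national
systems, coverage tracks the calibration of the posterior (~80% when the
model is well calibrated). Calibration checks in this package are run in
the latter regime (envelopes of 2×10⁵–10⁶, true PM 0.2–0.6%), where the
measured coverage is ~83%.

Errors are observed minus predicted median; relative errors in percent of
the observed value (zero observed PM excluded with a warning). Aggregates
are medians (ME, MAE, MRE, MARE) and the proportions of observations
below/above their 80% interval; for the leave-20% exercise, errors and
flags are first averaged within country, following the convention that
repeated observations of one country should not dominate.

## Synthetic worlds

`bmis.synthetic` draws complete truths from the generative process itself:
country latents from the hierarchy, per-year four-cell counts from the
multinomial, studies as non-overlapping 1–3-year periods whose cells are
summed and then *masked* to one of the three reporting patterns with the
empirical mix 72% / 19% / 9% (the observed 147/39/18 shares of study
records). Defaults: 15 countries × 20 years, 4 studies per country,
hyperparameters at the posterior medians reported for the UN-MMEIG global study database (global sensitivity
0.593, global specificity 0.9995, σ⁺ 0.599, σ⁻ 0.157, ρ 0.307, δ⁺ 0.117,
δ⁻ 0.131, φ −0.370), envelopes log-uniform over 10³–10⁵ with Poisson
year-to-year variation, true PM 0.3–2% with mild linear trends — the
regime where specificity near 0.999 materially moves the adjustment
factor.

Deliberate realism: multi-year studies aggregate years whose cell
probabilities *vary*, while the likelihood evaluates probabilities at the
midyear — the same mild misspecification real study reporting induces.
`constant_probs=True` freezes each study period at its midyear
probabilities for exact-model tests. What the generator does **not**
emulate: incomplete death registration, correlation of study placement
with data quality, reporting errors in the studies themselves, and any
resemblance to specific real countries — so passing tests demonstrate
correctness of the method under its own assumptions, not performance on
real CRVS data.

## Numerical and design choices

* Cell probabilities are floored at 1e−300 inside the samplers' likelihood
  so boundary proposals are effectively (not literally) impossible; the
  reference likelihood keeps exact −inf semantics.
* Probit round-trips are exact to 1e−12 except in the far upper tail
  (probabilities within ~1e−9 of 1), an inherent float64 limitation that
  is irrelevant at the specificities the data support (≤ 0.9999).
* `split_random` removes `round(0.2·n)` studies uniformly without
  replacement; all randomness flows from explicit integer seeds
  (`numpy.random.SeedSequence`), and fixed seeds reproduce fits
  bit-identically within a process.
* Validation predictions require a study-based PM, so partial-breakdown
  records (no confirmed total) are skipped in test sets — mirroring the
  fact that the 2015 procedure could not use them either.

## Known limitations

* The sampler is random-walk based; for very large study databases (many
  hundreds of studies) the production schedule would be slow, and a
  gradient-based backend would be preferable.
* Hyperparameter intervals from short desk-scale schedules can be flagged
  non-converged (split-R̂ > 1.1); the flag is reliable and such fits
  should be re-run with the production schedule before interpretation.
* Specificity is close to 1 in the regime of interest, so its posterior is
  sensitive to the handful of studies with false-positive breakdowns; with
  none present it is identified only through the overlap likelihood.
* No covariates: exploratory analyses on the global study database (GDP,
  fertility rate, ill-defined-cause share, ICD revision) found no usable
  relationships with sensitivity or specificity, and none are implemented.
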