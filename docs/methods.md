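# Methods

## Model and estimation

`mlvarnet` fits a multilevel vector autoregression of order one to
long-format experience-sampling data. Within a person-day, each of the J
observed items at beep *t* is regressed on all J items at beep *t−1*; the
day boundary resets the chain, so no pair spans a night, and the first
beep of a day appears only as a predictor. Every regression coefficient
(intercept and J lag weights) decomposes into a population fixed effect
and a person-specific random deviation, assumed multivariate normal with
mean zero and, by default, an unstructured covariance within each
equation.

The J equations are estimated separately as linear mixed models (REML,
via `statsmodels.MixedLM`) and the fixed effects re-indexed into the J×J
transition matrix Φ — a pseudo-likelihood scheme. Two consequences are
inherited deliberately:

- cross-equation random-effect covariances are not identified and not
  estimated;
- contemporaneous innovation correlations are only available indirectly;
  we estimate them as Pearson correlations of the stacked per-row
  conditional residuals, which casewise deletion guarantees are aligned
  across equations.

Wald tests on fixed effects use a standard-normal reference, appropriate
for the large within-person row counts of ESM designs; a
degrees-of-freedom correction (Satterthwaite) is not implemented.
Significance masks over the J² lag coefficients use either a raw α or
Benjamini–Hochberg FDR; intercepts and moderator main effects are never
part of that family.

### Assumptions

1. *Equal spacing within day.* Beeping schemes are quasi-random within
   fixed blocks; the model treats within-day intervals as equal.
   `interval_stats` reports the realized mean/SD of gaps between adjacent
   answered beeps (sample SD, day boundaries excluded) so users can judge
   the approximation.
2. *Stationarity within person-period.* Checked per person × variable ×
   period series with the KPSS level test, and globally by comparing
   summed BICs against a model with a person-specific linear trend in the
   beep number.
3. *Lag order one.* `lag_order_comparison` refits orders 1..k on the
   common row set usable at the highest order (so BICs are comparable),
   with random effects restricted to the intercept and lag-1 slopes.

### Missing data

A response row enters the design only when the beep with index exactly
one lower was answered the same day and both beeps are complete on all J
items (casewise deletion; gaps are never bridged, because a bridged pair
would violate the equal-interval approximation). The reduction report
states answered vs usable counts per person-period and the number of
pairs lost to item-level missingness. No imputation is performed.

## Moderators

*Therapy (local analysis).* The two-period model gives each lag
coefficient a post-baseline change term (controls) and a post × therapy ×
predictor three-way interaction; intercept analogues are included. Person
deviations of the intercept are estimated separately pre and post
(unstructured covariance between them); slope deviations are shared
across periods — people who deviate from the average dynamics at baseline
are assumed to keep doing so. The J² interaction p-values form one BH-FDR
family.

*Neuroticism (global analysis).* Sum scores are cut into an ordinal 0/1/2
group score — at the questionnaire's quartile-based boundaries (NEO-FFI
12–34 / 35–45 / 46–60; TIPI 1–2 / 2.5–4.5 / 5–7) or at the empirical
first/third quartiles — which interacts linearly with the baseline lag
coefficients only: Φ(g) = Γ + g·N. By default post-baseline rows stay in
the model with period main-effect and period × lag terms absorbing
post-baseline change; a `baseline_only` flag restricts to period-0 rows.
Therapy and neuroticism are separate models by design; requesting both at
once is refused.

## Centrality and its bootstrap

Betweenness is computed on the directed graph with edge k→j for every
nonzero Φ[j,k], self-loops removed, and distance 1/|weight| — link
strength is magnitude, sign is kept for display only. Brandes' algorithm
(networkx) gives equal fractional credit among tied shortest paths.
Weights of magnitude ≤ 1e-12 are treated as absent edges so that
numerically-zero coefficients cannot create spurious paths. By default
centrality uses the full weight matrix, not the significance-masked one;
a masked option exists.

Because re-estimating the mixed model ~1000 times is prohibitive, the
bootstrap runs on a fixed-effects-only linear model with the identical
moderated coefficient structure (its fixed estimates correlate > 0.9 with
the mixed model's on simulated data; the acceptance script recomputes
this agreement). Three steps: fit and keep fitted values + residuals;
resample residual *rows* with replacement (jointly across equations,
preserving contemporaneous correlation; per-equation resampling is a
flag) and add them to the fitted values; refit by projecting onto the
unchanged design matrix, assemble Φ(g) per group, compute betweenness.
Responses are perturbed but never re-lagged — a model-based, not dynamic,
bootstrap. Summaries are the median and plain percentile intervals
(50%/95% by default); BCa is not used. A fixed seed gives bit-identical
results.

## Diagnostics: numerical choices

- KPSS: level-stationarity null, Schwert-style short bandwidth
  ⌊4(T/100)^¼⌋ (configurable), p-values interpolated from the standard
  table and clamped to [0.01, 0.10]; constant series get statistic 0.
  Series shorter than 10 points are excluded from the stationarity
  proportion and counted separately.
- BIC: −2·loglik + k·log(n) per equation with k = fixed coefficients +
  free covariance parameters + 1 (residual variance) and n = design rows,
  summed over equations, always on identical row sets (asserted).

## Optimizer behavior

REML surfaces with near-boundary variance components can defeat a single
optimizer run. Each equation tries lbfgs, then up to three lbfgs restarts
from multiplicatively perturbed copies of the best parameters so far
(these are cheap and usually rescue boundary cases), then bfgs, then
Powell (warm-started, then cold). If an unstructured covariance never
converges the equation is refitted with a diagonal covariance and flagged
`simplified` in the result. Equations that fail outright leave NaN rows
in Φ and downstream network constructors refuse the partial model.

A constrained diagonal-covariance parametrization is exposed
(`RandomSpec("diagonal")`) but converges poorly under gradient
optimizers in the backend; the unstructured default is both the intended
model and, in practice, the faster fit.

## The simulator

`simulate_esm` draws, per person and equation, (intercept, slope)
deviations from the configured covariance — independently across
equations, mirroring exactly the structure the pseudo-likelihood fit can
identify (a `cross_equation_corr` option draws all deviations jointly for
robustness studies of that assumption). Person matrices with spectral
radius ≥ 0.98 are redrawn (up to 100 times, then deviations are halved
toward the population matrix); the 0.98 threshold avoids near-unit-root
series in short windows. Each day starts from the person's stationary
distribution (mean (I−Φ_p)⁻¹μ_p, covariance from the discrete Lyapunov
equation, with a 50-step burn-in fallback), then iterates
y_t = μ_p + Φ_p y_{t−1} + ε_t with multivariate-normal innovations.
Beeps are deleted independently at the missingness rate; clock times fall
uniformly within consecutive 90-minute blocks from 07:30.

Default conditions emulate a clinical ESM study's shape: 100 persons,
6 days × 10 beeps per period, six mood items on a 1–7 scale with
positive/negative valence clusters, self-loops 0.2, random-effect SDs 0.3
(intercept) / 0.1 (own lag) / 0.05 (cross lags), innovation variance 0.8
with valence-structured correlations, 18% beep missingness (≈49 of 60
beeps answered), neuroticism scores N(40.7, 7.4²) on the NEO-FFI scale,
and a 63/129 treated fraction. Values are continuous by default; Likert
clip-and-round quantization exists as an explicit model violation for
robustness studies.

What the generator does **not** emulate: circadian mean trends, response
styles, floor/ceiling censoring, informative missingness, unequal beep
spacing effects, and cross-equation random-effect correlation. Passing
recovery tests therefore demonstrate internal consistency of estimator
and model, not robustness to these real-data features.

## Problem sizes used in tests and the acceptance script

Chosen once as desk-scale versions of the study conditions: parameter
recovery runs 20 replicates at P=100 (bias and RMSE) and 10 replicates at
P=25 (RMSE consistency arm); the null-network FDR study uses 20
replicates of a 4-variable, 40-person design with random intercepts only
(matching its generator, which has no slope heterogeneity); KPSS
calibration uses 500 series of length 200; bootstrap contracts use 200
replicates. Unit tests run 3-variable studies of 12–60 persons.

## Known limitations

- Pseudo-likelihood SEs ignore cross-equation information; joint
  multivariate fitting and Bayesian alternatives are out of scope.
- BLUP-based individual networks are shrunken toward the population
  matrix; rank orderings are more trustworthy than absolute values.
- The bootstrap conditions on the observed predictor rows; it does not
  propagate uncertainty from the autoregressive design itself.
- Continuous-time (irregular-interval) models are out of scope; the
  equal-interval approximation is reported, not corrected.
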