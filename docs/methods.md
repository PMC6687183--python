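# Methods

This note documents the statistical models, the samplers, the synthetic-data
generator, and the numerical conventions used throughout `farmbayes`, along
with the design choices that were genuinely open and the limitations a user
should know before trusting a green test suite.

## Models

### Site-indexed Gaussian regression (yield, SPAD)

For plot `k` of household `j` at site `i`:

    Y_ijk = alpha_i + X_ijk beta_i + sigma eps_ijk,   eps ~ N(0, 1)

Both years of the panel are pooled into one fit.  Every model variable —
response, continuous covariates, and (by default) binary covariates — is
standardized to mean 0, SD 1 over the pooled sample (SD with the n-1
denominator), so coefficients are "beta weights" comparable across variables
and sites.  Binary standardization can be disabled
(`standardize(..., standardize_binaries=False)`) for sensitivity analysis.

Site-varying intercepts and slopes are implemented as one joint model with
indicator-expanded columns (`alpha[site]`, `beta[site][covariate]`) sharing a
single error scale `sigma`, matching the equation above; shared-coefficient
fits are available by flag.  Priors: coefficients iid `N(0,1)` (weakly
informative on the standardized scale), `sigma^2 ~ InvGamma(shape=2,
scale=1)` (finite prior mean 1, diffuse in practice on this scale).  Whether
the inverse-gamma sits on `sigma` or `sigma^2` is a convention; this package
puts it on the variance, and `log_posterior` reports the density over
`sigma` with the corresponding Jacobian.

The default yield model uses 12 explanatory variables: three seasonal
rainfall totals (Dec–Feb sowing, March, April–May harvest, mm), soil POXC
(mg C/kg) and pH, ridge spacing (m), weed biomass (kg/m^2), fertilizer use
(0/1), intercropping (0/1), compost/manure (0/1), plus SPAD and
farmer-reported striga (0/1).  The SPAD and striga models use the ten
environment/management variables.  A fertilizer *rate* (kg N/ha, computed by
`nitrogen_applied`: urea 46% N, local NPK 23% N, summed over applications
and divided by plot area) can replace the binary when raw application
records are available.

### Striga hurdle

The 0–8 enumerator striga count is zero-inflated (roughly two-thirds of
plots are striga-free), so a single linear model would be biased.  The
two-step hurdle separates:

1. **prevention** — Bayesian logistic regression of presence (count >= 1)
   over all plots;
2. **control** — the Gaussian model above on the 1–8 count, standardized
   *within the striga-positive subset*, fitted to that subset only.  The
   subset mean/SD are retained for back-transformation.

Step 2 subsets can be small (a few hundred plots against ~44 site-varying
parameters); the fit proceeds with a logged warning when the subset has
fewer than 10 rows per parameter, and such estimates lean on the prior.

### Household (farmer) screen

`y = alpha_h + sigma eps`, all sites pooled, no covariates, one intercept
per household with independent `N(0,1)` priors (dummy-variable style, not a
hierarchical shared-variance prior — the screen mirrors a fixed-effects
procedure, and partial pooling would change what "flagged" means).  The
response is standardized over the pooled sample first; the striga screen
uses the standardized 0–8 count by default (capturing presence and
intensity; a binary mode exists).  A household is flagged positive
(negative) at level L when `P(alpha_h > 0 | y)` is at least L (at most
1 - L).  No multiple-testing correction is applied across households — the
screen reports raw per-household credibility calls.

## Samplers

All kernels target the exact stated posterior; convergence is gated at
split-chain R-hat <= 1.1, computed per parameter.  Non-convergence flags the
result and logs a warning; it never raises or discards.

* **Gaussian models — conjugate Gibbs.**  Given `sigma^2`, the coefficient
  block is multivariate normal `(Z'Z/sigma^2 + I)^(-1)` geometry, sampled by
  Cholesky; given the coefficients, `sigma^2` is inverse-gamma.  With
  `fixed_sigma` the draws are iid from the closed-form conjugate posterior
  (used by the oracle tests and available as a calibration backend).
* **Logistic model — Laplace independence MH.**  The posterior mode and
  Hessian are found by damped Newton; proposals are multivariate-t (df 8)
  centered at the mode with the Laplace covariance.  Acceptance rates are
  ~0.35 at survey scale; rates below 0.15 log a warning.  Complete
  separation is detected heuristically (extreme fitted log-odds at the mode)
  and only warned about — the normal prior keeps the posterior proper.
* **Household screen — exact marginal sampler.**  Because the household
  intercepts enter disjoint row blocks, they integrate out analytically and
  the marginal posterior of `sigma^2` is one-dimensional; it is sampled iid
  by inverse-CDF on a 4096-point log-spaced grid, and `alpha_h | sigma^2` is
  Gaussian in closed form.  Flagging probabilities are Rao-Blackwellized
  (normal CDF averaged over `sigma^2` draws), which makes the screen exactly
  sign-equivariant and order-invariant.  Draws are arranged as 2 chains so
  the same diagnostics contract applies (R-hat ~ 1 by construction).

Defaults: 2 chains, 500 burn-in, 10,000 retained draws per chain, matching
the analysis this package operationalizes.  Every fit is reproducible from
(settings, seed); per-chain generators derive from a `SeedSequence` spawn.

### R-hat convention

Split-chain potential scale reduction: each chain is halved, and with `W`
the mean within-sequence variance and `B/n` the variance of sequence means,
`R-hat = sqrt(((n-1)/n W + B/n) / W)`.  Estimates marginally below 1 (pure
noise in the B/W ratio) are floored at 1.0; zero-variance chains return 1.0
by convention with a warning (degenerate but convergent).  ESS uses
FFT autocovariances with Geyer's positive-pair truncation.

## Synthetic generator

The generator emulates the survey the models were built for: 4 sites
(Golomoti, Linthipe, Kandeu, Nsipe), by default 80 households per site, 2
plots per household, 2 years — 1,280 potential plot-year records,
bracketing the ~1,197 analyzed in the source survey (an optional
missing-completely-at-random fraction thins records; the true missingness
mechanism is unreported, so MCAR with default 0 is used).

* **Covariates** are drawn independently per site: truncated normals for
  continuous variables (non-negative; pH in [3, 10]) and Bernoullis for
  binaries, with per-site means/SDs/probabilities taken from the survey's
  published descriptive table.  The truncated normals are *moment-matched*:
  the underlying location/scale are solved numerically so the
  post-truncation mean/SD equal the configured values — otherwise
  low-mean variables (weed biomass, April–May rain) would be visibly
  biased by the truncation.  Rainfall is a site-year variable (identical
  across plots within a site-year); POXC and pH are plot variables
  (constant across years, as plots were soil-sampled once).
* **Responses** follow the model family exactly.  Striga: presence from the
  logistic incidence model, then a 1–8 level from a linear predictor plus
  noise, rounded and clamped (preserving the linearity the control model
  assumes); the farmer-reported indicator is 1 iff the count is >= 1.  SPAD:
  the Gaussian model on the standardized scale, de-standardized with the
  configured pooled moments.  Yield: the 12-covariate Gaussian model, with
  realized SPAD and striga entering the predictor standardized by their
  realized pooled sample moments (matching what preprocessing will do),
  then de-standardized and floored at 0 kg/ha (floored count logged — a few
  percent of records under the default truth).  Optional household offsets
  (`household_sd > 0`) are drawn independently per response model.
* **Default truth** echoes the reported effect structure: SPAD is the
  dominant positive yield coefficient (+0.28 to +0.42 SD by site), striga
  the dominant negative one (to -0.38 at the wetter, high-yield sites);
  fertilizer raises SPAD everywhere except the marginal site, where POXC
  and compost matter instead; incidence intercepts reproduce the published
  per-site farmer-reported striga rates at covariate means.  Residual
  scales (sigma 0.7 for yield, 0.8 for SPAD on the standardized scale,
  level SD 1.5 on the 1–8 scale) were chosen once as realistic for noisy
  on-farm data (yield R^2 ~ 0.5) and are not tuned.
* The reported fertilizer–SPAD correlation arises structurally (fertilizer
  has a positive SPAD coefficient), not from a joint covariate draw.

**What the generator does not emulate:** spatial structure and GPS,
within-site rainfall variation (CHIRPS pixels differ by plot in reality —
consequently the per-site rainfall slopes of a 2-year synthetic panel are
identified only up to a 2-dimensional projection, and the prior fills the
rest), right-skewed yield distributions (Gaussian + floor instead),
informative missingness, and socio-economic covariates.  A green
parameter-recovery test therefore establishes sampler correctness on
model-consistent data, not robustness to real-survey pathologies.

### Scale caveat for recovery tests

The generator's truth is defined on the *configured* pooled-standardized
scale.  The realized response has sample variance != 1 (it inherits the
model's variance decomposition), so an analysis that re-standardizes the
response by sample moments rescales every coefficient by 1/SD(realized).
Recovery tests therefore compare posteriors against truth on the generator's
own scale; the pipeline's sample standardization is the right choice for
real data, where no "configured" scale exists.

## Acceptance quantities

* **t1 (convergence gate)**: max R-hat across all parameters of the three
  models on a full-size synthetic survey at the default MCMC settings;
  values land near 1.003, far under the 1.1 gate.
* **t2 (interval calibration)**: with coefficients and noise variance drawn
  from their priors, central 95% intervals must cover truth ~95% of the
  time — the defining frequentist property of correct Bayesian computation.
  Pooled over 200 datasets x 5 coefficients; reduced chains
  (2 x (200 + 1,500)) keep runtime down without affecting exactness of the
  Gibbs draws.
* **t3 (household-screen null rate)**: the screen applied to pure noise.
  Note a real calibration subtlety: with only 4 records per household, the
  N(0,1) intercept prior and the estimated sigma give the nominal-95%
  screen a true null flag rate of ~7% (measured ~7.4% over replicates),
  somewhat above the idealized 5%.  This is a property of the
  dummy-intercept screening procedure itself, reported as computed, not
  corrected away.  Screens also share the sigma posterior, so per-household
  flags are weakly dependent.

## Numerical conventions and degenerate inputs

* SDs use the n-1 denominator everywhere; standardization requires >= 2
  complete rows and errors on constant columns, naming the column.
* Empirical quantiles (credible intervals, summaries) use linear
  interpolation between order statistics (`numpy.quantile` default).
* Significance thresholds are closed (>= L, <= 1-L); posterior draws tied
  at exactly zero count as not-positive.
* Missing data: complete-case deletion with logged counts; dropped rows are
  reported on the design matrix (`n_dropped`).
* Hurdle preconditions: counts must be integers in 0..8 with both zero and
  non-zero strata present; an all-zero (or all-positive) striga column is an
  error, not a silent skip.
* Design pathologies: identically-zero columns raise; exactly proportional
  columns (a binary constant within one site, common on small hurdle
  subsets) and structural rank deficiency only warn — the coefficient prior
  keeps the posterior proper, at the cost of prior-identified directions.
* `log_posterior` is a pure function (no sampling) returning the fully
  specified log density; `sigma <= 0` returns -inf by contract.

## Known limitations

* No model comparison (WAIC/LOO), no correlated multi-response system
  (noise terms are independent across the three models by design), no
  endogeneity correction — management variables are farmer choices, so
  coefficients are associations, not causal effects.
* The logistic independence-MH kernel relies on a near-Gaussian posterior;
  with severe separation or tiny subsets its acceptance rate drops (logged)
  and draws lean on the proposal's t tails.  R-hat and the acceptance-rate
  warning are the guardrails.
* The household screen's nominal level is not its frequentist size (see
  t3 above); interpret flagged proportions relative to a simulated null,
  which the test suite and acceptance script both provide.
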