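# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter for
reproducing results.

## Indicator construction

The analytic denominator is the set of women aged 15–49 with a demand for
family planning: fecund women who want to space or limit childbearing,
plus all current contraceptive users (use reveals demand regardless of the
stated preference or fecundity fields). Among these women the binary
outcome mDFPS is true exactly when the current method belongs to the
configured modern list. Pregnant non-users are classified as having no
current demand by default — they cannot currently use a method — with a
configuration switch (`pregnancy_rule="mistimed"`) that counts them as in
demand when a `pregnancy_mistimed` field is supplied and true. The full
DHS unmet-need revision-9 algorithm (postpartum amenorrhoea windows,
contraceptive-failure timing) is deliberately not reconstructed; the
one-sentence definition above is the contract, and the simplification is
visible in the vocabulary/pregnancy configuration.

The default modern list is pills, male and female condoms, injectables,
implants, patch, diaphragm, spermicides and emergency contraception, plus
IUD and male/female sterilisation. The last three follow the DHS
convention; some published definitions omit them, so their inclusion is
logged at vocabulary creation and is configurable. Unknown method codes
always raise — a typo must never silently count as "not modern".

Records missing fecundity or fertility preference (when those fields are
needed) are excluded and counted in a JSON report, never silently dropped.

## Design-weighted descriptives

Point estimates are Hajek ratios Σwx/Σw. Variances use Taylor
linearization with clusters as primary sampling units under the
with-replacement first-stage approximation — the standard estimator for
DHS-type indicators when, as here, cluster membership is the only design
information available. Confidence intervals are computed on the logit
scale and back-transformed so they stay inside [0, 1]; degenerate
estimates (p = 0 or 1, or a single cluster) return collapsed or undefined
intervals rather than extrapolating. Stratification is not modelled:
exact CI widths are therefore implementation-defined, and comparisons
against software that uses strata will differ slightly.

## Three-level logistic model

logit P(y=1) = β₀ + β′x + u_region + v_cluster, with independent Normal
random effects. Priors: Normal(0, 10²) on every coefficient (weakly
informative on the logit scale), half-Normal(0, 1) on both random-effect
standard deviations (admits essentially any plausible survey ICC while
regularising the zero-variance boundary). The likelihood is unweighted:
sampling weights enter the descriptive estimates only. Default reference
levels are urban residence, age 35–49, secondary-or-higher education, male
household head, richest wealth quintile, in union, Islam, parity 3–4.

Sampling is adaptive Hamiltonian Monte Carlo on a non-centred
parameterisation (random effects expressed as standard-normal vectors
scaled by their sd, hyper-sds on the log scale with the Jacobian included).
The warmup schedule tunes the step size by dual averaging to a 0.8
acceptance target, estimates a diagonal mass matrix from a middle warmup
window, then re-tunes the step size under that metric; trajectory lengths
are jittered uniformly over the upper half of `max_leapfrog`. Defaults:
2 chains × 400 warmup + 400 kept draws. The fit fails loudly when the
split-R̂ of any reported parameter — the coefficients and both variance
components — exceeds 1.05, or when more than 10 % of kept transitions
diverge. Complete separation of a covariate level triggers a warning
naming the level.

Odds-ratio tables report posterior means of exp(β) with central 95 %
credible intervals; variance components are summarised on the variance
scale.

## Matérn Gaussian-process binomial model

Women are collapsed to cluster-level counts (x_i successes out of N_i
demand-positive women); only raster covariates enter this model, extracted
at cluster coordinates and standardized with the raster's own recorded
mean/sd so that fit-time and prediction-time transforms coincide exactly.
The latent field S has Matérn covariance with smoothness ν fixed at 3/2
(closed-form kernel, a common model-based-geostatistics default; ν is
configurable and recorded in outputs). Coordinates live in a projected km
plane, so the range φ is in km and distances are Euclidean.

Priors: Normal(0, 10²) on coefficients; half-Normal(0, 1) on the marginal
sd σ; log-normal on φ with median one fifth of the cluster-cloud diameter
and log-sd 1 — weakly informative and scaled to the study area, since a
range far beyond the domain is not identifiable from within it.

Inference is exact (dense-Cholesky) MCMC on the non-centred form
S = σ L(φ) z: HMC moves (β, z, log σ), and φ is drawn by griddy-Gibbs on a
fixed logarithmic grid of 41 points spanning ±2.5 prior log-sd. Two exact
full-conditional draws are interleaved in the ancillarity–sufficiency
pattern: one holds z fixed (the field re-realises under each candidate φ;
binomial likelihood recomputed), one holds S fixed (z re-expressed; the
likelihood cancels and only the whitened prior, Jacobian and hyperprior
remain). A sufficient-scale random-walk move on log σ with warmup-adapted
scale completes the sweep. The grid bounds the number of distinct Cholesky
factorizations (cached) and eliminates the sticky behaviour of continuous
random-walk updates on this weakly identified parameter. Chains start from
empirical-logit residuals of the cluster counts, which places the latent
field in the data-supported basin; with diffuse latent starts the
(σ, φ) pair can wander into a large-range/large-variance local trap.

σ² and φ are individually weakly identified (their posterior concentrates
along the σ²/φ^2ν ridge; only that combination is well determined at
fixed domain size). The hard convergence gate (split-R̂ ≤ 1.05, divergence
fraction ≤ 10 %) therefore applies to the reported regression
coefficients; slow-mixing hyperparameters raise a warning and their R̂/ESS
are always available in `diagnostics_`.

Prediction: for each kept posterior draw the conditional Gaussian
(kriging) equations give the latent mean and covariance at pixel centres
given the latent values at cluster sites; a fresh conditional-noise vector
is drawn, the covariate linear predictor added, and the inverse logit
applied. Pixels are masked to the admin-polygon union by centre-in-polygon
membership. Grids larger than `tile_size` (default 2048) pixels are
predicted in tiles with exact means; the conditional noise is then sampled
independently across tiles, which leaves pixel-level summaries exact but
slightly understates the covariance of aggregates spanning tiles — grids
used in the shipped analyses fit in one tile. Co-located clusters are
merged by summing counts (identical coordinates make the correlation
matrix singular); the Cholesky jitter starts at the configured nugget
(default 1e-6 on the correlation scale) and escalates tenfold a bounded
number of times before failing with the condition number.

## Post-processing

Area values are per-draw means of member pixels (centre-in-polygon;
boundary ties go to the lowest area id), unweighted by default with an
optional non-negative per-pixel weight layer (e.g. population density).
The national value is the same mean over all unmasked pixels, so with
uniform weights the national draw equals the pixel-count-weighted mean of
area draws exactly. Exceedance probability uses the strict inequality:
EP(t) = fraction of draws > t; the WHO target default is t = 0.75.

Between-period change pairs draws from the two independently fitted
posteriors by independent resampling with a recorded seed
(n_pairs = min(n₁, n₂)); this makes "identical posteriors → EP ≈ 0.5" the
null behaviour, which is the interpretation the EP is given. Index
pairing is available when draw counts match, but under it identical
posteriors give EP = 0 (no strictly positive differences), so it is not
the default. The MPC is the mean of per-draw differences in percentage
points; progress labels are improving (EP ≥ 0.9), reversing (EP ≤ 0.1),
indeterminate otherwise.

## Synthetic-data generator

The generator emulates a paired two-round DHS-like study: a square study
region tiled into rectangular admin units, clusters placed uniformly
within regions (allocation proportional to area), women per cluster with
categorical covariates drawn from configurable marginals (defaults
approximate a rural East-African respondent profile), log-normal sampling
weights (sd 0.3, normalised to mean 1), and a Bernoulli outcome from a
linear predictor assembled from named coefficients — "intercept",
woman-level dummies ("field=level"), and raster-layer names — plus either
nested Normal region/cluster effects or a Matérn GP at cluster
coordinates. A configurable fraction of women (default 16 %) have no
demand (infecund, wanting a child soon, or pregnant) and are excluded from
the analytic denominator. Raw contraception fields are back-filled to be
consistent with the simulated outcome, so the indicator module
reconstructs the intended flags exactly (verified at 100 % in tests); the
intended flags are kept in `sim_demand`/`sim_mdfps`, and the realized
latent term per cluster in `sim_latent`.

Covariate rasters are low-frequency random fields (bicubically upsampled
coarse Gaussian noise) transformed to realistic ranges: education years
and population density positive, care-seeking and poverty probabilities in
[0, 1], mean parity non-negative.

In a two-period bundle, period 2 adds `period_shift` to the linear
predictor, optionally only inside a named set of regions (a regionally
localized improvement). By default the two periods share one latent
spatial realization, drawn jointly over both periods' cluster locations —
real coverage maps show geographic patterns that persist between rounds,
and without a shared field the independent realizations masquerade as
±20-point regional "changes". Setting `shared_field=False` restores fully
independent rounds.

What the generator does not emulate — and hence what passing tests do not
establish about real data: cluster-coordinate displacement, stratified and
unequal-probability sampling designs (weights are independent noise),
item non-response patterns, the full unmet-need algorithm's
pregnancy-timing fields, non-stationary or anisotropic spatial structure,
and country-shaped (non-rectangular) geographies.

## Default problem sizes

Study conditions in the shipped tests and acceptance runs: a 160 km square
(so a 25 km-range field contains ~40 independent patches, enough to
identify σ²) with 8–10 regions; multilevel recovery at 400 clusters × 25
women over 20 replicates; geostatistical recovery at 300 clusters × ~25
demand-positive women; end-to-end change detection at 160 clusters × 20
women per period over 10 seeds with a 10 km prediction grid. MCMC sizes
default to 2 chains with 400–600 warmup and 300–500 kept draws; surface
cubes use 120–200 draws. These sizes give stable split-R̂ for all gated
parameters and Monte Carlo error well inside the tolerance of every check
that consumes them.

## Known limitations

* The geostatistical model is dense-Cholesky (O(n³) in clusters): suitable
  for survey-scale data (≲ 1000 clusters), not for tens of thousands of
  points.
* φ is restricted to its prior grid; posterior statements about the range
  are discretized at ~6 % resolution in φ.
* Surveys weights are ignored in both Bayesian models (likelihoods are
  unweighted); weighted results appear only in the descriptive tables.
* EP and MPC inherit Monte Carlo error of order 1/√n_draws; with the
  default 200 surface draws an EP near 0.5 carries ±0.07 (2 se).
* Separate-period fits mean the MPC does not exploit any between-period
  correlation; its credible intervals are conservative when the rounds
  share structure.
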