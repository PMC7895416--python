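# Methods

## Problem and model

The package estimates childhood (ages 5–17) obesity prevalence for small
geographic areas — zip codes — from individual-level EHR-style records that
cover some areas densely, some sparsely, and some not at all. Four linked
problems are addressed: (i) subject-level risk varies with covariates and
with neighborhood; (ii) BMI is recorded only for a biased subset of children;
(iii) many zip codes contribute too few subjects for a stable direct
estimate; (iv) uncertainty must reflect the entire estimation chain.

**Subject-level model.** A logistic mixed model with a census-block-group
random intercept:

    logit P(obese_i = 1) = x_i' β + b_{g(i)},   b_g ~ N(0, σ²),

with covariates age (years), sex (male vs female), Medicaid and no-insurance
(vs commercial), and a White non-Hispanic indicator (vs non-white/Hispanic).
The covariate set is configurable. The block-group intercept absorbs
neighborhood-level correlation (shared socioeconomic environment, facilities).

**Missingness.** P(BMI observed | X) is modeled by logistic regression on
the full cohort with candidate covariate blocks age, race, insurance,
urbanicity, and the economic hardship index (EHI). Backward elimination with
a P < 0.05 retention rule removes one covariate at a time — the block with
the largest p-value, tested by a likelihood-ratio test of the model with and
without the whole block (multi-level factors are one block: dropping a
single dummy of a factor is not a meaningful reduction). Ties at machine
precision drop the block declared later. Each observed subject then carries
weight 1/p̂(X): themself plus 1/p̂(X) − 1 similar unobserved subjects.

**Aggregation.** For a zip-by-sex cell, prevalence is the weighted mean of
model-predicted individual probabilities over the cell's observed subjects,
Σ w_i p̂_i / Σ w_i, with p̂_i = expit(x_i'β̂ + b̂_g) using the predicted
(conditional-mode) random intercept of the subject's block group, and b̂ = 0
for block groups unseen in fitting.

**Small areas.** Zips with fewer than `min_n = 20` observed subjects
(counted across both sexes — the threshold describes the zip's data supply,
not a single cell) get Nadaraya–Watson estimates: a Gaussian-kernel weighted
average of the *direct* estimates of data-rich donor zips, distance being
the absolute difference of scalar community-similarity indices. The zip's
similarity index is the areal-weighted mean of block-group similarity
scores (weights = fraction of zip area covered; weights must sum to 1,
renormalized only within 1e-6). Donors are always direct estimates —
smoothed values never feed other targets, so synthetic estimates cannot
propagate. The bandwidth defaults to the normal-reference rule
h = 1.06·min(sd, IQR/1.34)·n^(−1/5) applied to the similarity indices of
all zips participating in the smoothing step (donors and targets); it can be
overridden numerically. A Gaussian kernel matches the normal-reference rule;
if all kernel weights underflow the single nearest donor is used and the
event logged.

**Uncertainty.** Percentile bootstrap with subject-level resampling: each
replicate redraws N subjects with replacement and re-runs the entire chain
(missingness fit with selection, mixed model, aggregation, smoothing); the
95% interval for a cell is the 2.5%/97.5% empirical quantile pair (linear
interpolation between order statistics) of its replicate estimates.
Replicate r is seeded from (base_seed, r), so results are reproducible and
order-independent. A `fixed_weights` mode reuses the original missingness
model instead of re-fitting per replicate; the full re-fit is the default so
intervals include selection and weighting variability. Replicates where a
model cannot be fit (e.g. a resample loses an outcome class) are dropped and
counted; above 10% failures the run aborts because the surviving percentile
interval would be untrustworthy.

## Fitting algorithms and numerics

**Mixed model.** The fitter maximizes the Laplace approximation to the
marginal likelihood. For fixed σ, Newton iterations maximize the joint
penalized log-likelihood over (β, b); the random-intercept Hessian block is
diagonal, so each step is solved through a p×p Schur complement at O(n p²)
cost. The profiled Laplace deviance

    −2 [ ℓ(y; β̂_σ, b̂_σ) − Σ_g b̂_g²/(2σ²) − ½ Σ_g log(1 + σ² W_g) ]

(W_g the summed IRLS weights of group g at the mode) is minimized over σ by
bounded one-dimensional search on [1e-4, 5] (absolute tolerance 1e-5, inner
Newton gradient tolerance 1e-9, zero starting values — fits are run-to-run
deterministic). If the boundary σ = 0 is at least as good, the model
collapses exactly to ordinary logistic regression. This is the fast
joint-mode Laplace variant (as in lme4's nAGQ=0 scheme); on simulated data
fixed effects agree with glmer's default Laplace fit to a small fraction of
a standard error (cross-checked in the test suite). Standard errors are the
(β, β) block of the inverse joint Hessian. With a single block group the
random intercept is unidentified and the fit falls back to plain logistic
regression with a warning. Wald odds-ratio tables use OR = exp(β̂),
CI = exp(β̂ ± 1.959964·SE).

**Logistic core.** All ordinary logistic fits use a Newton–Raphson core
with step halving (gradient tolerance 1e-10, ≤50 iterations). It exists
because the bootstrap re-fits the missingness and obesity models tens of
thousands of times; per-fit overhead of a general-purpose modeling library
dominates at that scale. Estimates, standard errors and log-likelihoods
agree with statsmodels to ~1e-8 (asserted in tests). Zero-variance columns
(an empty factor level in a resample) are excluded from the optimization and
reported with coefficient 0; this keeps resampling robust without changing
identifiable estimates.

**Separation.** Perfect or quasi-perfect separation leaves the likelihood
without a finite maximizer; the saturated stratum's fitted probabilities pin
to 0/1 while the gradient vanishes, so convergence alone cannot detect it.
A fit is flagged separated when a coefficient's magnitude (scaled by its
column's SD, or raw for rare strata) exceeds a plausibility bound. Primary
missingness fits raise an error naming the offending covariate. Inside
bootstrap replicates the pipeline instead proceeds with the capped fit: for
weighting purposes separation is benign (p̂ → 1 gives weight 1; p̂ → 0 is
truncated by the weight floor), and with a ~0.4% no-insurance stratum,
resamples of a few thousand subjects separate by chance regularly enough
that aborting them would bias the bootstrap. The weight floor is
p_floor = 0.01 (maximum weight 100), with truncations counted and logged.

## Synthetic populations

The generator produces data with exactly the structure the analysis
assumes, so every stage can be validated against known truth:

* **Geography.** `n_blockgroups` block groups partitioned among `n_zips`
  zips as "core" members (each zip gets ≥ 1), plus extra overlaps at rate
  `overlap_density`; Dirichlet area fractions per zip (core concentration
  4.0 vs 0.8) sum to 1. Each block group carries an EHI uniform on its
  range, a similarity score with Gaussian-copula correlation `sim_ehi_corr`
  (default 0.5) to the EHI — community similarity tracks low-SES features in
  real data — and an urbanicity class (30% urban / 45% suburban / 25% rural).
* **Individuals.** Uniform assignment to block groups by default; setting
  `blockgroup_concentration` draws Dirichlet population shares instead, so
  small values reproduce the very uneven geographic coverage of a single
  health system's records (data-rich core zips, data-poor and zero-data
  periphery — the regime the smoothing stage exists for). a subject's zip is
  their block group's maximal-overlap zip (ties to the smallest zip id).
  Age is uniform on the integers 5–17 (observed cohort mean 10.84 ≈ the
  uniform mean 11; no age distribution is published). Sex, race and
  insurance are independent draws matching the published cohort marginals
  (male 0.515, White non-Hispanic 0.817, Medicaid 0.169, uninsured 0.004).
* **Outcome.** Bernoulli through the logistic mixed model with default
  fixed effects at the published magnitudes (age 0.041, male 0.257,
  Medicaid 0.543, no-insurance −0.171, white −0.516) and intercept −2.10,
  chosen so marginal prevalence sits near the published 13.6%;
  σ defaults to 0.3. `intercept_similarity_corr` optionally couples b_g to
  the block group's standardized similarity score, making similarity
  genuinely informative about prevalence — the premise kernel smoothing
  relies on.
* **Missingness.** Bernoulli observation through a logistic model whose
  default coefficients follow the published directions (higher EHI, rural
  residence, no insurance, and White non-Hispanic race all lower the
  observation probability); intercept 1.6 puts the observation rate near
  0.6, typical of BMI completeness in pediatric EHR extracts.
* **Streams.** Randomness is split per purpose (geography / covariates /
  random effects / outcomes / missingness) from one seed, so changing the
  missingness model never changes the cohort.

What the generator does **not** emulate: spatial polygon geometry, within-zip
correlation beyond the block-group intercept, longitudinal visits,
continuous BMI values, age-dependent covariate structure, or correlated
covariates (e.g. insurance by race). Passing tests therefore show the
estimator chain is correct *under its own assumptions*, not that those
assumptions hold in any particular EHR.

## Validation scales

Simulation-based checks run at sizes chosen to keep the full suite
practical while preserving power: parameter recovery at n = 40,000 with 200
block groups and σ = 0.3 over 20 replicates; IPW bias correction at
n = 20,000 over 50 replicates with EHI-driven missingness coupled to the
outcome through similarity-correlated intercepts (sim_ehi_corr = 0.9,
intercept_similarity_corr = 0.9, σ = 0.5, γ_EHI = −0.04) — under the
default uncoupled configuration the missingness bias is too small for the
comparison to be informative; selection calibration at n = 20,000 over 200
MCAR replicates (a 20-replicate binary check of a ~5% retention rate false-
alarms on roughly a third of seed sets, so the retention rate is estimated
from 200 runs against the same ≤10% bound); bootstrap coverage on 100
datasets of n = 2,000 across 30 zips with B = 200 replicates, evaluating
whether the interval covers the median-data zip's true prevalence — the
realized (sex-averaged) obesity rate of that zip's full cohort, unobserved
children included. The realized rate, not the cohort-mean model
probability, is the surveillance quantity a zip interval is for; the
probability-mean target strips the zip's own outcome noise and makes any
reasonable interval over-cover.

## Known limitations

* The Laplace joint-mode profile slightly underestimates σ² for binary
  outcomes with few subjects per group (a known property of this
  approximation class); fixed effects are essentially unaffected at the
  scales tested.
* IPW corrects only missingness explainable by the modeled covariates
  (missing-at-random given X); outcome-dependent missingness is not
  identifiable from these data.
* The similarity index is consumed as a given scalar per block group; its
  construction from census measures is out of scope, as is deriving
  urbanicity classes or geocoding addresses.
* Smoothed estimates are only as good as the donor pool: if data-rich areas
  differ systematically from data-poor ones, smoothing transfers that bias
  (visible in this design as a widening estimate gap as similarity distance
  grows).
* Obesity enters as a precomputed binary flag; classifying BMI against
  growth-chart percentiles requires external reference tables and is out of
  scope.
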