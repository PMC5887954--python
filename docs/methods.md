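# Methods

## The problem

In a meta-analysis of randomized trials that each recorded a repeated
continuous outcome (e.g. systolic blood pressure) together with a
censored event time (e.g. time to death), the two outcomes are usually
correlated: subjects whose longitudinal trajectory deviates from the
population mean may be at altered event risk, and events truncate the
longitudinal follow-up (informative dropout). `metajoint` implements a
two-stage analysis of such data: stage 1 fits a model to each study's
individual participant data; stage 2 pools the study-level coefficients
with standard inverse-variance meta-analysis. The package's purpose is
to provide both stage-1 arms — *separate* longitudinal and survival
models, and the *joint* shared-random-effects model — plus the pooling
machinery and a simulation harness that measures when the joint arm is
worth its computational cost.

## Stage-1 models

**Separate arm.** The longitudinal outcome follows a linear mixed model

    Y_kij = x_kij' β₁k + z(t_kij)' b_ki + ε_kij,
    b_ki ~ N(0, Σ_k),  ε_kij ~ N(0, σ²_k),

with subject-level random intercept (optionally + slope) independent of
the error. Estimation is full maximum likelihood, *not* REML: the joint
model maximizes a likelihood, and ML makes the zero-association
decoupling between the two arms exact. The default optimizer maximizes
the exact marginal Gaussian likelihood with the fixed effects profiled
out by GLS, grouping subjects by visit pattern so the per-pattern
marginal covariance is factorized once per objective evaluation; a
statsmodels `MixedLM` backend is available and agrees to optimizer
tolerance. Fixed-effect standard errors come from the inverse
information `(Σᵢ Xᵢ'Vᵢ⁻¹Xᵢ)⁻¹` at the MLE.

The event time follows a Cox proportional-hazards model
`λ_ki(t) = λ₀k(t) exp(x_ki' β₂k)` with unspecified baseline hazard.
The partial likelihood is maximized by Newton's method with step
halving; ties use the Breslow approximation and the baseline cumulative
hazard is the Breslow step-function estimator. Breslow (rather than
Efron) was chosen because the joint model's EM baseline update is
Breslow-type, keeping the two arms' baselines comparable. Standard
errors are the inverse observed information of the partial likelihood.

**Joint arm.** The two submodels share the zero-mean random effects
through a *proportional association*:

    λ_ki(t) = λ₀k(t) exp(x_ki' β₂k + α_k · z(t)' b_ki),

so a single scalar α_k converts a subject's deviation from the
population trajectory (intercept + slope, evaluated at event time
rather than measurement time) into log-hazard. α > 0 means subjects
above the population mean trajectory are at elevated risk. Alternative
association structures (current value, slope) carry different
interpretations and are deliberately not implemented; pooling across
structurally different joint models is the one thing the stage-2 module
actively refuses to do (see *grouped pooling* below).

### EM algorithm

The observed-data likelihood per subject is
`∫ f(Y|b) f(T, δ|b) φ(b; 0, Σ) db` with the survival factor
`[λ₀(T)e^{η(b)}]^δ exp(−Σ_{t_j ≤ T} λ₀j e^{η_j(b)})` over baseline mass
points. The fit alternates:

* **E-step.** The conditional density of `b_i` is the Gaussian
  posterior from the longitudinal data alone, tilted by the survival
  likelihood. We integrate by adaptive Gauss–Hermite quadrature centered
  and scaled at that Gaussian posterior; after the transform the
  posterior weights reduce to (GH weight) × (survival likelihood at the
  node), and the observed-data log-likelihood is the *exact* Gaussian
  longitudinal marginal plus a log quadrature sum over the smooth
  survival factor. Because the residual variance is small relative to
  the random-effect variance in the intended regime, the posterior is
  tight and low orders are already accurate: on reference-condition
  studies, 3 points/dimension matches 9 points/dimension to ~1e-4 on
  all parameters. The standalone default is 9 points/dimension; the
  simulation harness uses 3 (its `FitControl.quad_points`).
* **M-step.** β₁, σ², Σ have closed-form updates from the posterior
  moments; the baseline increments have a Breslow-type update
  `λ₀j = d_j / Σ_{i∈R_j} e^{x_i'β₂} E_i[e^{α z_j' b}]`; (β₂, α) take a
  step-halved Newton update on the expected survival log-likelihood
  (two inner baseline/Newton passes per EM iteration).

Initialization is the separate LMM + Cox fit with α = 0 (which also
makes the ascent comparison against the initializer meaningful).
Convergence is declared when the maximum relative parameter change
drops below 1e-5 (default; denominator |θ|+0.01), capped at 200
iterations with a logged convergence flag.

Plain EM converges slowly along the Σ↔α direction (hundreds of
iterations at this tolerance), so every second iteration the fit
attempts an Aitken-style extrapolation along the last step difference,
accepted only if the observed-data log-likelihood does not decrease.
This preserves the monotone-likelihood property (asserted in tests to
−1e-6 per step, the integration tolerance) while roughly halving
iteration counts and typically reaching a slightly higher optimum.

### Standard errors

Profile/information-based standard errors are known to be
underestimated in semiparametric joint models, so joint-model SEs come
from a nonparametric bootstrap: subjects resampled with replacement
within study, each replicate refit warm-started from the full-data
estimates, SE = SD of replicate estimates, normal-approximation CI by
default (percentile optional). Replicates with zero events are redrawn
(logged; >50% redraws aborts). Replicate r draws its RNG from the
substream (seed, r), so results are reproducible and independent of
execution order.

## Stage-2 pooling

Fixed-effect pooling: `θ̂ = Σwθ̂_k/Σw`, `w_k = 1/v_k`,
`SE = (Σw)^{-1/2}`, Wald CI with the z-quantile computed exactly from
the level (1.959964…, which matters for reproducing published numbers
to their printed rounding). Heterogeneity: Cochran's
`Q = Σw_k(θ̂_k − θ̂_F)²`, DerSimonian–Laird
`τ² = max(0, (Q − (K−1)) / (Σw − Σw²/Σw))`, `I² = max(0, (Q−df)/Q)`,
p-value from χ²_{K−1}. Random-effects pooling re-weights by
`1/(v_k + τ²)`. No Hartung–Knapp or REML τ² variants are provided.
Study rows published as CIs are converted by
`SE = (upper − lower)/(2 z)`, so aggregate-data pooling needs no IPD.

Grouped pooling partitions estimates by a user-declared group label
(intended to encode the joint-model structure) and pools strictly
within groups — association parameters from structurally different
joint models measure different things and must not be averaged.

## Synthetic data

The generator reproduces the reference simulation conditions: K = 5
studies × 500 subjects randomized 1:1; visits at t = 0…4 kept strictly
before the survival time; longitudinal fixed effects (intercept, time,
treatment) = (1, 3, 2); random-effect covariance
[[0.9, 0.5], [0.5, 1.2]]; residual variance 0.01. Event times are
Gompertz with subject-level log-scale θ₀ + αb₀ and shape θ₁ + αb₁, and
treatment log-hazard 3; when the realized shape is negative the
distribution is defective and with the corresponding probability the
subject's event time is infinite (a cure fraction — this is what makes
higher association levels reduce event rates). Censoring is
exponential, rate exp(−3.08) ("high" event-rate regime) or exp(−0.58)
("low"), with an independent uniform draw. (θ₀, θ₁) are calibrated once
by moment matching so the reference-arm, zero-random-effect event time
has mean 3 and SD 1; the calibration exploits that ρ = e^{θ₀}/θ₁ alone
determines the coefficient of variation (a 1-D root find), with θ₁ then
set by the mean. A Gompertz can only represent SD ≤ mean; SD = mean is
returned as the exponential limit θ₁ = 0.

Heterogeneous-effect scenarios draw per-study treatment coefficients
from N(2, 0.5) and N(3, 0.5), reading the second argument as a
*variance* (consistent with the N(0, Σ)/N(0, σ²) notation elsewhere);
`het_spread` exposes the value so the SD reading is also runnable.
Uniform draws for event and censoring times are independent.

**What the generator does not emulate:** the measured event proportions
under these exact parameters are ≈92% (high regime) and ≈43% (low) at
α = 0 — higher than the regimes' nominal ~75%/~25% labels, because a
treatment log-hazard of 3 makes treated subjects fail almost
immediately while control subjects (mean event time 3) are rarely
censored even at the low censoring rate. We keep the published
parameter values rather than re-tuning the censoring rates to the
nominal labels; the regime *ordering* (high > low for every α, matched
seeds) is what the comparisons rely on, and it holds. The generator
also does not produce missing visits, measurement-schedule differences
between studies, or covariates beyond treatment, so passing tests say
nothing about robustness to those features of real data.

## Simulation harness

A replicate = simulate K studies → fit both arms per study (joint SEs
by bootstrap) → pool each parameter (β₁₂, β₂₁, α) by fixed and random
MA. A scenario aggregates replicates into mean estimate, empirical SE
(SD of pooled estimates) and CI coverage of the generating value (under
heterogeneity, the mean of the effect distribution). Any per-study fit
failure marks the replicate failed; failed replicates are excluded from
metric denominators and counted. The full factorial grid is 5
association levels × 2 event-rate regimes × {homogeneous,
heterogeneous} = 20 scenarios, each replicate keyed by (scenario seed,
replicate index) so any scheduler can run and merge them.

Inside the harness, bootstrap SEs only feed pooling weights, so
`FitControl` defaults to 50 bootstrap draws rather than the ~200 a
standalone analysis would use, and is configurable in both directions.

## Problem sizes used by the shipped runs

The per-dataset generative conditions (5 × 500, visit grid, parameter
values) are never scaled. Replicate counts and bootstrap draws are:
`scripts/acceptance.py` uses 32 replicates with 5 bootstrap draws and
3 quadrature points/dimension for the recovery study; the test-suite
recovery check uses 20 replicates with a 5-draw bootstrap, and the
bias/coverage contrast uses 100 matched replicates with a 3-draw
bootstrap and coarse EM tolerance (1e-3) — the contrast being measured
is roughly one log-hazard unit, far above that resolution. Monte-Carlo error bands in tests
are computed from the replicates actually run. With few bootstrap
draws the joint CIs are noisy (coverage lands below the nominal 95%);
the contrast against the separate arm's collapsed coverage at strong
association is insensitive to this.

## Numerical choices and edge cases

* Quadrature: product Gauss–Hermite, ≥2 points/dimension enforced;
  order-refinement agreement is tested (9 vs 18 points within 1e-4).
* Baseline increments are floored at 1e-300 before logs; the Newton
  step falls back to a scaled gradient if the Hessian is singular.
* Longitudinal measurements exactly at the survival time are excluded
  (strict `t < T`), matching the capping rule of the generator;
  duplicate (subject, time) rows are rejected, not averaged.
* Missing outcomes are dropped row-wise at read time; the joint model
  itself is the mechanism for handling the informative part of dropout.
* `τ²` and `I²` are truncated at 0; a single-study "meta-analysis" is
  allowed for the fixed model only.
* Random-number policy: every stochastic component (generator,
  bootstrap, harness) derives independent substreams from
  `SeedSequence([seed, key])`; equal seeds give bit-identical output.

## Known limitations

* One longitudinal outcome, no competing risks, no time-varying
  exogenous covariates in the hazard, no frailty or stratified
  baselines.
* Only the shared-zero-mean-random-effects association; no
  current-value or slope structures.
* The EM's observed-data log-likelihood is monotone only up to
  quadrature error; with very diffuse longitudinal information (few
  measurements per subject and large σ²) the adaptive rule would need
  more points than the defaults.
* DerSimonian–Laird with a plain χ² heterogeneity test is known to be
  anti-conservative for very small K; no small-K correction is applied
  because the reference results use the plain estimator.
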