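# metajoint

Two-stage meta-analysis of joint longitudinal and time-to-event data.

Trials that follow a repeated continuous outcome (blood pressure, a
biomarker) alongside a censored event time usually analyse the two
separately — a linear mixed model and a Cox model. When the outcomes
are associated (subjects deviating from the population trajectory are
at altered event risk, and events cut follow-up short), the separate
Cox analysis omits a subject-level frailty and its treatment effect is
attenuated. A *joint model* links the submodels through shared
zero-mean random effects with a proportional association:

    Y_kij  = x_kij' β₁k + z(t_kij)' b_ki + ε_kij          b_ki ~ N(0, Σ_k)
    λ_ki(t) = λ₀k(t) exp( x_ki' β₂k + α_k · z(t)' b_ki )

Study k's coefficients (β₁₂k, β₂₁k, α_k) are then pooled across studies
by inverse-variance meta-analysis — fixed-effect weights 1/v_k, or
DerSimonian–Laird random-effects weights 1/(v_k + τ²) with Q, τ², I²
heterogeneity statistics. `metajoint` provides both stage-1 arms
(separate and joint, the latter fitted by EM with a nonparametric
baseline hazard and bootstrap standard errors), the stage-2 pooling
machinery (which also consumes published aggregate rows, no IPD
needed), a data generator for the reference simulation conditions, and
a harness measuring bias / empirical SE / CI coverage of each arm
across association strengths.

It is aimed at biostatisticians running IPD meta-analyses of
longitudinal + survival trial data, and at methodologists who want the
simulation evidence reproduced or extended.

## Worked example

Pooling the published per-study treatment effects on systolic blood
pressure from the INDANA hypertension trials (time-to-death analysis;
six study rows entered as estimate + 95% CI):

```python
from metajoint import pool_fixed, pool_random, dl_heterogeneity
from metajoint.datasets import indana_effects

ests = indana_effects("death", "beta12", "separate")
fixed, random = pool_fixed(ests), pool_random(ests)
Q, tau2, I2, p = dl_heterogeneity(ests)
print(f"fixed:  {fixed.pooled:.2f} ({fixed.ci[0]:.2f}, {fixed.ci[1]:.2f})")
print(f"random: {random.pooled:.2f} ({random.ci[0]:.2f}, {random.ci[1]:.2f})")
print(f"Q = {Q:.1f}, tau2 = {tau2:.4f}, I2 = {100*I2:.1f}%, p = {p:.2g}")
```

```
fixed:  -8.67 (-8.95, -8.38)
random: -9.86 (-11.39, -8.33)
Q = 105.5, tau2 = 3.2063, I2 = 95.3%, p = 3.7e-21
```

Treatment lowers SBP by ~9–10 mmHg under either pooling model; the
large I² (95%) says most of the between-study spread is real
heterogeneity, so the wider random-effects interval is the honest one.

Why the joint model matters — one simulated study with a true
association of 0.5 and a true treatment log-hazard ratio of 3:

```python
from metajoint import ScenarioConfig, simulate_study, fit_cox, fit_joint
from metajoint.simulate import LOW_EVENT_RATE_LAMBDA

cfg = ScenarioConfig(alpha=0.5, lambda_cens=LOW_EVENT_RATE_LAMBDA,
                     n_per_study=200, seed=1).with_calibration()
study, truth = simulate_study(cfg, 0)
separate = fit_cox(study)
joint = fit_joint(study, quad_points=5)
print(f"separate Cox log-HR: {separate.beta_[0]:.2f}")
print(f"joint log-HR: {joint.beta2_[0]:.2f}, association alpha: {joint.alpha_:.3f}")
```

```
separate Cox log-HR: 2.27
joint log-HR: 3.09, association alpha: 0.560
```

The separate Cox fit attenuates the treatment effect (2.27 vs the true
3); the joint fit recovers it and estimates the association. The
harness (`run_scenario`, `scenario_grid`) repeats this comparison over
replicates and scenarios and reports mean estimates, empirical SEs and
coverage per method × parameter × pooling model.

## Command line

```bash
metajoint simulate --config scenario.yaml --out data/ --seed 7
metajoint pool --estimates estimates.csv --model both --out forest.csv
metajoint run-study --reps 100 --seed 1 --out results/
```

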