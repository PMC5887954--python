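"""Simulation-study orchestration: replicate-level two-stage analyses and
scenario-level operating characteristics.

One *replicate* = one simulated meta-dataset (K studies), analysed by
the methods of interest (separate LMM + Cox per study, and/or the joint
model per study with bootstrap SEs), with each parameter pooled by fixed
and random-effects meta-analysis.  A *scenario* aggregates many
replicates into the mean pooled estimate, the empirical SE (SD of the
pooled estimates across replicates), and the coverage of the pooled CI
against the generating value.  Replicates are independent jobs keyed by
(scenario seed, replicate index), so any scheduler can run and merge
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cox import CoxProportionalHazards
from .joint import (
    DEFAULT_JOINT_SPEC,
    JointSpec,
    SharedRandomEffectsJointModel,
    bootstrap_joint,
)
from .lmm import LinearMixedModel
from .pooling import EffectEstimate, MetaAnalysis
from .simulate import (
    HIGH_EVENT_RATE_LAMBDA,
    LOW_EVENT_RATE_LAMBDA,
    ScenarioConfig,
    simulate_meta_dataset,
)

logger = logging.getLogger(__name__)

PARAMETERS = ("beta12", "beta21", "alpha")


@dataclass
class FitControl:
    """Stage-1 fitting knobs for the simulation harness.

    ``n_boot`` is deliberately smaller than a standalone analysis would
    use: inside the harness the bootstrap SEs only feed pooling weights,
    for which a modest number of replicates is adequate.  ``quad_points``
    is Gauss–Hermite points per random-effect dimension.
    """

    n_boot: int = 50
    quad_points: int = 9
    max_iter: int = 200
    tol: float = 1e-5
    boot_max_iter: int = 40
    boot_tol: float = 1e-4
    level: float = 0.95


@dataclass
class ReplicateResult:
    replicate_id: int
    failed: bool
    table: pd.DataFrame  # method, parameter, model, pooled, se, lo, hi, tau2
    error: str | None = None


def _extract_joint_estimates(study, fit, boot, spec) -> dict[str, EffectEstimate]:
    names = fit.param_names_
    i_treat_long = names[0].index("treat")
    i_treat_surv = names[1].index("treat")
    return {
        "beta12": EffectEstimate(
            study.study_id, "beta12",
            float(fit.beta1_[i_treat_long]),
            boot.se["beta1_treat"] ** 2,
        ),
        "beta21": EffectEstimate(
            study.study_id, "beta21",
            float(fit.beta2_[i_treat_surv]),
            boot.se["beta2_treat"] ** 2,
        ),
        "alpha": EffectEstimate(
            study.study_id, "alpha", fit.alpha_, boot.se["alpha"] ** 2
        ),
    }


def run_replicate(
    config: ScenarioConfig,
    replicate_seed: int,
    methods: Sequence[str] = ("separate", "joint"),
    control: FitControl | None = None,
    spec: JointSpec = DEFAULT_JOINT_SPEC,
) -> ReplicateResult:
    """Simulate one meta-dataset and run the full two-stage analysis.

    Any per-study fit failure marks the whole replicate failed (recorded,
    not raised).  The separate method contributes beta12 (LMM,
    information SE) and beta21 (Cox, information SE); the joint method
    contributes beta12, beta21 and alpha with bootstrap SEs.
    """
    control = control or FitControl()
    config = replace(config, seed=int(replicate_seed)).with_calibration()
    dataset, _truth = simulate_meta_dataset(config)
    per_method: dict[str, dict[str, list[EffectEstimate]]] = {
        m: {p: [] for p in PARAMETERS} for m in methods
    }
    try:
        for k, study in enumerate(dataset):
            lmm = LinearMixedModel(spec.lmm_spec).fit(study)
            cox = CoxProportionalHazards(spec.survival_covariates).fit(study)
            if "separate" in methods:
                i = lmm.param_names_.index("treat")
                per_method["separate"]["beta12"].append(
                    EffectEstimate(
                        study.study_id, "beta12",
                        float(lmm.beta_[i]), float(lmm.se_beta_[i]) ** 2,
                    )
                )
                j = cox.param_names_.index("treat")
                per_method["separate"]["beta21"].append(
                    EffectEstimate(
                        study.study_id, "beta21",
                        float(cox.beta_[j]), float(cox.se_beta_[j]) ** 2,
                    )
                )
            if "joint" in methods:
                init = {
                    "beta1": lmm.beta_,
                    "beta2": cox.beta_,
                    "alpha": 0.0,
                    "Sigma": lmm.Sigma_,
                    "sigma2": lmm.sigma2_,
                    "baseline": {
                        "time": cox.baseline_["time"].to_numpy(),
                        "increment": cox.baseline_["increment"].to_numpy(),
                    },
                }
                jm = SharedRandomEffectsJointModel(
                    spec,
                    quad_points=control.quad_points,
                    max_iter=control.max_iter,
                    tol=control.tol,
                ).fit(study, init=init)
                boot = bootstrap_joint(
                    study,
                    spec,
                    n_boot=control.n_boot,
                    seed=int(np.random.SeedSequence(
                        [replicate_seed, k]).generate_state(1)[0] % (2**31)),
                    level=control.level,
                    fitted=jm,
                    quad_points=control.quad_points,
                    max_iter=control.boot_max_iter,
                    tol=control.boot_tol,
                )
                for p, e in _extract_joint_estimates(study, jm, boot, spec).items():
                    per_method["joint"][p].append(e)
    except Exception as exc:  # failed fit: record, don't raise
        logger.warning("replicate %d failed: %s", replicate_seed, exc)
        return ReplicateResult(replicate_seed, True, pd.DataFrame(), str(exc))

    rows = []
    for method, by_param in per_method.items():
        for param, ests in by_param.items():
            if not ests:
                continue  # separate method has no alpha entries
            for model in ("fixed", "random"):
                ma = MetaAnalysis(model, control.level).fit(ests)
                rows.append(
                    {
                        "method": method,
                        "parameter": param,
                        "model": model,
                        "pooled": ma.pooled_,
                        "se": ma.se_,
                        "ci_lower": ma.ci_[0],
                        "ci_upper": ma.ci_[1],
                        "tau2": ma.tau2_,
                    }
                )
    return ReplicateResult(replicate_seed, False, pd.DataFrame(rows))


@dataclass
class ScenarioMetrics:
    config: ScenarioConfig
    n_reps: int
    n_failed: int
    table: pd.DataFrame  # method, parameter, model, mean_estimate, empirical_se, coverage

    def cell(self, method: str, parameter: str, model: str) -> pd.Series:
        t = self.table
        m = (
            (t["method"] == method)
            & (t["parameter"] == parameter)
            & (t["model"] == model)
        )
        return t.loc[m].iloc[0]


def true_values(config: ScenarioConfig) -> dict[str, float]:
    """Generating values used as coverage truths.  Under heterogeneity the
    truth is the mean of the effect distribution."""
    return {"beta12": config.beta12, "beta21": config.beta21, "alpha": config.alpha}


def summarize_replicates(
    results: Sequence[ReplicateResult], config: ScenarioConfig
) -> ScenarioMetrics:
    ok = [r for r in results if not r.failed]
    if not ok:
        raise RuntimeError("all replicates failed")
    truth = true_values(config)
    stacked = pd.concat(
        [r.table.assign(replicate_id=r.replicate_id) for r in ok],
        ignore_index=True,
    )
    rows = []
    for (method, param, model), g in stacked.groupby(
        ["method", "parameter", "model"], sort=False
    ):
        tv = truth[param]
        cover = ((g["ci_lower"] <= tv) & (tv <= g["ci_upper"])).mean()
        rows.append(
            {
                "method": method,
                "parameter": param,
                "model": model,
                "mean_estimate": g["pooled"].mean(),
                "empirical_se": g["pooled"].std(ddof=1),
                "coverage": float(cover),
                "mean_tau2": g["tau2"].mean(),
                "n_reps": len(g),
            }
        )
    return ScenarioMetrics(
        config=config,
        n_reps=len(results),
        n_failed=sum(r.failed for r in results),
        table=pd.DataFrame(rows),
    )


def run_scenario(
    config: ScenarioConfig,
    n_reps: int,
    base_seed: int = 0,
    methods: Sequence[str] = ("separate", "joint"),
    control: FitControl | None = None,
) -> ScenarioMetrics:
    """Run ``n_reps`` independent replicates and aggregate.

    Replicate r uses the derived seed from (base_seed, scenario seed, r),
    so scenarios and replicates have non-overlapping streams.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    results = []
    for r in range(n_reps):
        rep_seed = int(
            np.random.SeedSequence([base_seed, config.seed, r]).generate_state(1)[0]
            % (2**31)
        )
        results.append(run_replicate(config, rep_seed, methods, control))
    return summarize_replicates(results, config)


def scenario_grid(
    alphas: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    event_rates: Sequence[str] = ("high", "low"),
    heterogeneity: Sequence[bool] = (False, True),
    base_seed: int = 0,
    **overrides,
) -> list[ScenarioConfig]:
    """The full factorial of scenarios (default 5 x 2 x 2 = 20), each with
    a distinct derived seed."""
    lam = {"high": HIGH_EVENT_RATE_LAMBDA, "low": LOW_EVENT_RATE_LAMBDA}
    configs = []
    idx = 0
    for het in heterogeneity:
        for rate in event_rates:
            for a in alphas:
                seed = int(
                    np.random.SeedSequence([base_seed, 7, idx]).generate_state(1)[0]
                    % (2**31)
                )
                configs.append(
                    ScenarioConfig(
                        alpha=a,
                        lambda_cens=lam[rate],
                        heterogeneous=het,
                        seed=seed,
                        **overrides,
                    )
                )
                idx += 1
    return configs


def export_results(
    metrics: Sequence[ScenarioMetrics], path=None
) -> pd.DataFrame:
    """Long-format scenario x method x parameter x model x metric table."""
    if not metrics:
        raise ValueError("need at least one scenario")
    frames = []
    for m in metrics:
        t = m.table.copy()
        t.insert(0, "alpha", m.config.alpha)
        t.insert(1, "lambda_cens", m.config.lambda_cens)
        t.insert(2, "heterogeneous", m.config.heterogeneous)
        t.insert(3, "scenario_seed", m.config.seed)
        t["n_failed"] = m.n_failed
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    if path is not None:
        out.to_csv(path, index=False)
    return out
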