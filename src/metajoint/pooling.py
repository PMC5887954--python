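"""Stage-2 pooling: inverse-variance fixed-effect and DerSimonian–Laird
random-effects meta-analysis with heterogeneity statistics.

Each study contributes an :class:`EffectEstimate` (point estimate and
variance for one named parameter).  Fixed-effect pooling weights by
1/v_k; random-effects pooling adds the method-of-moments between-study
variance tau^2 and weights by 1/(v_k + tau^2).  Heterogeneity is
summarized by Cochran's Q, tau^2, I^2 and a chi-squared p-value.
Published aggregate rows reported as confidence intervals can be
converted to standard errors with :func:`ci_to_se`, so study-level
results can be pooled without individual participant data.

Studies fitted with structurally different joint models (different
association structures or random-effect designs) estimate association
parameters with different interpretations; :func:`pool_grouped` pools
strictly within user-declared groups and never across them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class EffectEstimate:
    """One study's estimate of one parameter: the currency passed from
    stage 1 to stage 2."""

    study_id: str
    parameter: str
    estimate: float
    variance: float
    group: str | None = None

    def __post_init__(self):
        if not (np.isfinite(self.estimate) and self.variance > 0):
            raise ValueError("estimate must be finite and variance positive")

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate under one pooling model, with heterogeneity stats."""

    model: str  # "fixed" | "random"
    parameter: str
    pooled: float
    se: float
    ci: tuple[float, float]
    level: float
    weights: dict[str, float]  # normalized to sum to 1
    K: int
    Q: float
    df: int
    tau2: float
    I2: float
    het_pvalue: float


def ci_to_se(lower: float, upper: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric Wald confidence interval:
    (upper - lower) / (2 z_{(1+level)/2})."""
    if upper <= lower:
        raise ValueError("upper must exceed lower")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    return float((upper - lower) / (2 * z))


def _check(estimates: Sequence[EffectEstimate]):
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    params = {e.parameter for e in estimates}
    if len(params) > 1:
        raise ValueError(f"mixed parameter labels: {sorted(params)}")
    groups = {e.group for e in estimates}
    if len(groups) > 1:
        raise ValueError("mixed groups; use pool_grouped")
    return params.pop()


class MetaAnalysis(BaseEstimator):
    """Inverse-variance meta-analysis estimator.

    Parameters
    ----------
    model : {"fixed", "random"}
        Fixed-effect pooling, or DerSimonian–Laird random-effects pooling.
    level : float
        Confidence level for the Wald interval (z-quantile computed
        exactly from the level).

    After ``fit(estimates)`` the attributes ``pooled_``, ``se_``, ``ci_``,
    ``weights_``, ``Q_``, ``tau2_``, ``I2_``, ``het_pvalue_`` are set;
    :meth:`result` packages them as a :class:`MetaResult`.
    """

    def __init__(self, model: str = "fixed", level: float = 0.95):
        self.model = model
        self.level = level

    def fit(self, estimates: Sequence[EffectEstimate]) -> "MetaAnalysis":
        if self.model not in ("fixed", "random"):
            raise ValueError("model must be 'fixed' or 'random'")
        param = _check(estimates)
        K = len(estimates)
        est = np.array([e.estimate for e in estimates])
        v = np.array([e.variance for e in estimates])
        w_f = 1.0 / v
        pooled_f = float((w_f * est).sum() / w_f.sum())
        if K >= 2:
            Q = float((w_f * (est - pooled_f) ** 2).sum())
            df = K - 1
            denom = w_f.sum() - (w_f**2).sum() / w_f.sum()
            tau2 = max(0.0, (Q - df) / denom)
            I2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
            p = float(stats.chi2.sf(Q, df))
        else:
            if self.model == "random":
                raise ValueError("random-effects pooling needs >= 2 studies")
            Q, df, tau2, I2, p = 0.0, 0, 0.0, 0.0, float("nan")
        w = w_f if self.model == "fixed" else 1.0 / (v + tau2)
        pooled = float((w * est).sum() / w.sum())
        se = float(w.sum() ** -0.5)
        z = stats.norm.ppf(0.5 + self.level / 2)
        self.parameter_ = param
        self.K_ = K
        self.pooled_ = pooled
        self.se_ = se
        self.ci_ = (pooled - z * se, pooled + z * se)
        self.weights_ = {
            e.study_id: float(wk / w.sum()) for e, wk in zip(estimates, w)
        }
        self.Q_, self.df_, self.tau2_, self.I2_, self.het_pvalue_ = Q, df, tau2, I2, p
        return self

    def result(self) -> MetaResult:
        return MetaResult(
            model=self.model,
            parameter=self.parameter_,
            pooled=self.pooled_,
            se=self.se_,
            ci=self.ci_,
            level=self.level,
            weights=self.weights_,
            K=self.K_,
            Q=self.Q_,
            df=self.df_,
            tau2=self.tau2_,
            I2=self.I2_,
            het_pvalue=self.het_pvalue_,
        )


def pool_fixed(estimates: Sequence[EffectEstimate], level: float = 0.95) -> MetaResult:
    return MetaAnalysis("fixed", level).fit(estimates).result()


def pool_random(estimates: Sequence[EffectEstimate], level: float = 0.95) -> MetaResult:
    return MetaAnalysis("random", level).fit(estimates).result()


def dl_heterogeneity(
    estimates: Sequence[EffectEstimate],
) -> tuple[float, float, float, float]:
    """(Q, tau2, I2, p) from the DerSimonian–Laird moment estimator."""
    if len(estimates) < 2:
        raise ValueError("heterogeneity undefined for fewer than 2 studies")
    ma = MetaAnalysis("fixed").fit(estimates)
    return ma.Q_, ma.tau2_, ma.I2_, ma.het_pvalue_


def pool_grouped(
    estimates: Sequence[EffectEstimate], level: float = 0.95
) -> dict[str, dict[str, MetaResult | None]]:
    """Pool strictly within association-structure groups, never across.

    Returns ``{group: {"fixed": MetaResult, "random": MetaResult | None}}``;
    random-effects pooling is flagged unavailable (None) for single-study
    groups.
    """
    if any(e.group is None for e in estimates):
        raise ValueError("every estimate must carry a group label")
    out: dict[str, dict[str, MetaResult | None]] = {}
    for g in sorted({e.group for e in estimates}):
        sub = [e for e in estimates if e.group == g]
        fixed = pool_fixed(sub, level)
        random = pool_random(sub, level) if len(sub) >= 2 else None
        out[g] = {"fixed": fixed, "random": random}
    return out


def forest_table(
    estimates: Sequence[EffectEstimate],
    fixed: MetaResult,
    random: MetaResult | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Tabular forest-plot data: per-study rows with CIs and normalized
    percentage weights under each model, summary rows, and a heterogeneity
    footer row."""
    _check(estimates)
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for e in estimates:
        rows.append(
            {
                "row_type": "study",
                "study_id": e.study_id,
                "estimate": e.estimate,
                "ci_lower": e.estimate - z * e.se,
                "ci_upper": e.estimate + z * e.se,
                "weight_fixed_pct": 100 * fixed.weights.get(e.study_id, np.nan),
                "weight_random_pct": (
                    100 * random.weights.get(e.study_id, np.nan)
                    if random
                    else np.nan
                ),
            }
        )
    for res in (fixed, random):
        if res is None:
            continue
        rows.append(
            {
                "row_type": f"pooled_{res.model}",
                "study_id": "",
                "estimate": res.pooled,
                "ci_lower": res.ci[0],
                "ci_upper": res.ci[1],
                "weight_fixed_pct": np.nan,
                "weight_random_pct": np.nan,
            }
        )
    het = {
        "row_type": "heterogeneity",
        "study_id": "",
        "estimate": np.nan,
        "ci_lower": np.nan,
        "ci_upper": np.nan,
        "weight_fixed_pct": np.nan,
        "weight_random_pct": np.nan,
        "Q": fixed.Q,
        "tau2": fixed.tau2,
        "I2": fixed.I2,
        "het_pvalue": fixed.het_pvalue,
    }
    rows.append(het)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV interchange for aggregate-data pooling
# ---------------------------------------------------------------------------

def effects_from_frame(df: pd.DataFrame, level: float = 0.95) -> list[EffectEstimate]:
    """Build estimates from a table with columns ``study_id``, ``parameter``,
    ``estimate`` and one of ``variance``, ``se``, or ``ci_lower``/``ci_upper``
    (converted at ``level``); optional ``group``."""
    out = []
    for _, r in df.iterrows():
        if "variance" in df.columns and pd.notna(r.get("variance")):
            var = float(r["variance"])
        elif "se" in df.columns and pd.notna(r.get("se")):
            var = float(r["se"]) ** 2
        else:
            var = ci_to_se(float(r["ci_lower"]), float(r["ci_upper"]), level) ** 2
        out.append(
            EffectEstimate(
                study_id=str(r["study_id"]),
                parameter=str(r["parameter"]),
                estimate=float(r["estimate"]),
                variance=var,
                group=(str(r["group"]) if "group" in df.columns and pd.notna(r.get("group")) else None),
            )
        )
    return out


def read_effects_csv(path, level: float = 0.95) -> list[EffectEstimate]:
    return effects_from_frame(pd.read_csv(path), level=level)
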