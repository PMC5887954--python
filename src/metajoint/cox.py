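"""Cox proportional-hazards model with Breslow tie handling.

The separate time-to-event model is ``lambda_i(t) = lambda_0(t) exp(x_i' beta)``
with an unspecified baseline hazard.  The partial likelihood is maximized
by Newton's method with step halving; ties are handled with the Breslow
approximation and the baseline cumulative hazard is estimated by the
Breslow step-function estimator, placing mass only at observed event
times.  This matches the Breslow-type baseline update used inside the
joint model's EM algorithm, keeping the two analysis arms comparable.
Standard errors come from the inverse observed information of the partial
likelihood.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import StudyData


class CoxFitError(ValueError):
    """Degenerate survival data (no events, or a constant covariate)."""


def _prepare(df: pd.DataFrame, covariates):
    T = df["surv_time"].to_numpy(dtype=float)
    delta = df["event"].to_numpy(dtype=int)
    X = df.loc[:, list(covariates)].to_numpy(dtype=float)
    return T, delta, X


def breslow_partial_loglik(beta, T, delta, X) -> float:
    """Breslow-approximation partial log-likelihood (reference form).

    Direct implementation of
    ``sum_j [ s_j' beta - d_j log sum_{i in R(t_j)} exp(x_i' beta) ]``
    over distinct event times t_j, with s_j the covariate sum of the d_j
    events at t_j and R(t_j) the at-risk set.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    total = 0.0
    for tj in np.unique(T[delta == 1]):
        ev = (T == tj) & (delta == 1)
        risk = T >= tj
        total += eta[ev].sum() - ev.sum() * np.log(np.exp(eta[risk]).sum())
    return float(total)


class CoxProportionalHazards(BaseEstimator):
    """Semiparametric proportional-hazards model for one study.

    Parameters
    ----------
    covariates : sequence of str
        Covariate columns of the survival table entering the linear
        predictor (default the treatment indicator alone).

    Fitted attributes: ``beta_``, ``se_beta_``, ``baseline_`` (DataFrame of
    event times and Breslow hazard increments), ``partial_loglik_``,
    ``converged_``.
    """

    def __init__(self, covariates=("treat",), max_iter: int = 50, tol: float = 1e-10):
        self.covariates = tuple(covariates)
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, study: StudyData | pd.DataFrame) -> "CoxProportionalHazards":
        df = study.survival if isinstance(study, StudyData) else study
        T, delta, X = _prepare(df, self.covariates)
        if delta.sum() == 0:
            raise CoxFitError("no events observed")
        for j, name in enumerate(self.covariates):
            if np.ptp(X[:, j]) == 0:
                raise CoxFitError(f"covariate {name!r} is constant")

        order = np.argsort(-T, kind="stable")  # decreasing time
        T, delta, X = T[order], delta[order], X[order]
        p = X.shape[1]
        beta = np.zeros(p)
        ll = self._loglik_score_hess(beta, T, delta, X)[0]
        converged = False
        for _ in range(self.max_iter):
            ll, score, hess = self._loglik_score_hess(beta, T, delta, X)
            step = np.linalg.solve(hess, score)
            # step halving to guarantee ascent
            for _ in range(30):
                cand = beta + step
                ll_new = self._loglik_score_hess(cand, T, delta, X)[0]
                if ll_new >= ll - 1e-12:
                    break
                step = step / 2
            beta = cand
            if np.abs(score).max() < self.tol or abs(ll_new - ll) < 1e-12:
                converged = True
                break
        ll, score, hess = self._loglik_score_hess(beta, T, delta, X)
        self.beta_ = beta
        cov = np.linalg.inv(hess)
        self.se_beta_ = np.sqrt(np.diag(cov))
        self.cov_ = cov
        self.partial_loglik_ = float(ll)
        self.converged_ = converged
        self.baseline_ = self._breslow_baseline(beta, T, delta, X)
        self.param_names_ = list(self.covariates)
        return self

    @staticmethod
    def _loglik_score_hess(beta, T, delta, X):
        # T sorted decreasing: cumulative sums over rows give risk-set sums
        eta = X @ beta
        eta = eta - eta.max()  # overflow guard; cancels in ratios and loglik diffs
        w = np.exp(eta)
        S0 = np.cumsum(w)
        S1 = np.cumsum(w[:, None] * X, axis=0)
        S2 = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)
        # Breslow ties: every event at time t uses the full risk set {T >= t}.
        # With decreasing sort, the risk set for row i is rows 0..last index
        # sharing T[i]; take the cumulative sum at the last tied position.
        last = np.searchsorted(-T, -T, side="right") - 1
        ev = delta == 1
        idx = last[ev]
        ll = eta[ev].sum() - np.log(S0[idx]).sum()
        xbar = S1[idx] / S0[idx, None]
        score = X[ev].sum(axis=0) - xbar.sum(axis=0)
        v = S2[idx] / S0[idx, None, None] - xbar[:, :, None] * xbar[:, None, :]
        hess = v.sum(axis=0)  # observed information
        return ll, score, hess

    @staticmethod
    def _breslow_baseline(beta, T, delta, X) -> pd.DataFrame:
        eta = X @ beta
        w = np.exp(eta)
        S0 = np.cumsum(w)
        last = np.searchsorted(-T, -T, side="right") - 1
        times = np.unique(T[delta == 1])
        inc = np.empty_like(times)
        for k, tj in enumerate(times):
            ev = (T == tj) & (delta == 1)
            inc[k] = ev.sum() / S0[last[np.argmax(ev)]]
        return pd.DataFrame({"time": times, "increment": inc})

    def to_dict(self) -> dict:
        return {
            "beta2": dict(zip(self.param_names_, self.beta_.tolist())),
            "se_beta2": dict(zip(self.param_names_, self.se_beta_.tolist())),
            "partial_loglik": self.partial_loglik_,
            "converged": self.converged_,
            "baseline": self.baseline_.to_dict(orient="list"),
        }


def fit_cox(study: StudyData, covariates=("treat",)) -> CoxProportionalHazards:
    """Functional wrapper over :class:`CoxProportionalHazards`."""
    return CoxProportionalHazards(covariates).fit(study)
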