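"""Maximum-likelihood linear mixed models for the longitudinal outcome.

The longitudinal submodel is

    Y_ij = x_ij' beta + z_ij' b_i + eps_ij,   b_i ~ N(0, Sigma),  eps ~ N(0, sigma2)

with subject-level random effects ``b_i`` (random intercept, optionally a
random slope in time) independent of the measurement error.  Estimation is
by full maximum likelihood (not REML) so that, when the association with
the survival outcome is zero, the joint model's likelihood decouples
exactly into this marginal likelihood plus the survival likelihood.

Fitting is delegated to :class:`statsmodels` ``MixedLM`` (ML mode); the
exact Gaussian marginal log-likelihood is also implemented directly
(:func:`lmm_marginal_loglik`) and serves as an independent check surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import StudyData


class SingularFitError(ValueError):
    """Design matrix rank deficient or random effects unidentifiable."""


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedTerm:
    """One column of the fixed-effects design, as a named function of the
    long-format data (``time`` plus covariate columns)."""

    name: str
    fn: Callable[[pd.DataFrame], np.ndarray]

    @staticmethod
    def intercept() -> "FixedTerm":
        return FixedTerm("intercept", lambda df: np.ones(len(df)))

    @staticmethod
    def time() -> "FixedTerm":
        return FixedTerm("time", lambda df: df["time"].to_numpy(dtype=float))

    @staticmethod
    def covariate(name: str) -> "FixedTerm":
        return FixedTerm(name, lambda df: df[name].to_numpy(dtype=float))

    @staticmethod
    def transform(name: str, fn: Callable[[pd.DataFrame], np.ndarray]) -> "FixedTerm":
        """Arbitrary basis function, e.g. ``exp(-3 t)`` change-point terms."""
        return FixedTerm(name, fn)


@dataclass(frozen=True)
class LmmSpec:
    """Design specification shared by the separate LMM and the joint model.

    The random-effects design is restricted to functions of time alone
    (intercept, or intercept + slope) so it can be re-evaluated at the
    survival time when shared with the hazard submodel.
    """

    fixed: tuple[FixedTerm, ...] = field(
        default_factory=lambda: (
            FixedTerm.intercept(),
            FixedTerm.time(),
            FixedTerm.covariate("treat"),
        )
    )
    random_slope: bool = True

    @property
    def n_random(self) -> int:
        return 2 if self.random_slope else 1

    @property
    def fixed_names(self) -> list[str]:
        return [t.name for t in self.fixed]

    def design(self, df: pd.DataFrame) -> np.ndarray:
        """Fixed-effects design matrix X for long-format rows."""
        return np.column_stack([t.fn(df) for t in self.fixed])

    def random_design(self, times: np.ndarray) -> np.ndarray:
        """Random-effects design Z evaluated at arbitrary times."""
        t = np.asarray(times, dtype=float)
        if self.random_slope:
            return np.column_stack([np.ones_like(t), t])
        return np.ones((t.size, 1))


DEFAULT_SPEC = LmmSpec()


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class LinearMixedModel(BaseEstimator):
    """ML linear mixed model for one study's longitudinal table.

    Parameters
    ----------
    spec : LmmSpec
        Fixed and random effects design.
    backend : {"profile", "statsmodels"}
        "profile" (default) maximizes the exact marginal likelihood
        directly, profiling the fixed effects by GLS and grouping
        subjects that share a measurement-time pattern (fast on
        fixed-visit-grid data).  "statsmodels" delegates to MixedLM in ML
        mode; the two agree to optimizer tolerance and cross-check each
        other in the test-suite.

    Fitted attributes: ``beta_`` (fixed effects), ``Sigma_`` (random-effect
    covariance), ``sigma2_`` (residual variance), ``se_beta_``, ``loglik_``
    (maximized marginal log-likelihood), ``converged_``.
    """

    def __init__(self, spec: LmmSpec = DEFAULT_SPEC, backend: str = "profile"):
        self.spec = spec
        self.backend = backend

    def fit(self, study: StudyData) -> "LinearMixedModel":
        long = study.longitudinal
        if long["subject_id"].nunique() < 2:
            raise SingularFitError("need >= 2 subjects to separate random effects")
        X = self.spec.design(long)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SingularFitError("fixed-effects design matrix is rank deficient")
        y = long["outcome"].to_numpy(dtype=float)
        Z = self.spec.random_design(long["time"].to_numpy())
        if self.backend == "statsmodels":
            self._fit_statsmodels(long, X, y, Z)
        else:
            self._fit_profile(long, X, y, Z)
        self.param_names_ = self.spec.fixed_names
        return self

    def _fit_statsmodels(self, long, X, y, Z):
        import statsmodels.api as sm

        model = sm.regression.mixed_linear_model.MixedLM(
            y, X, groups=long["subject_id"].to_numpy(), exog_re=Z
        )
        with np.errstate(all="ignore"):
            res = model.fit(reml=False, method=["lbfgs", "cg"], maxiter=500)
        self.beta_ = np.asarray(res.fe_params, dtype=float)
        self.Sigma_ = np.asarray(res.cov_re, dtype=float)
        self.sigma2_ = float(res.scale)
        self.se_beta_ = np.asarray(res.bse_fe, dtype=float)
        self.loglik_ = float(res.llf)
        self.converged_ = bool(res.converged)

    # -- direct ML with profiled fixed effects -------------------------
    def _fit_profile(self, long, X, y, Z):
        from scipy import optimize

        d = self.spec.n_random
        # group subjects by measurement-time pattern: V_i identical within
        groups = long.groupby("subject_id", sort=False).indices
        keys = {}
        for sid, idx in groups.items():
            t = long["time"].to_numpy()[idx]
            keys.setdefault(tuple(np.round(t, 10)), []).append(idx)
        patterns = []
        for t, idxs in keys.items():
            idx = np.array(idxs)  # (n_subj, n_times)
            patterns.append(
                (
                    self.spec.random_design(np.asarray(t)),  # Z_p
                    X[idx],  # (s, m, p)
                    y[idx],  # (s, m)
                )
            )
        p = X.shape[1]
        N = len(y)

        def profile(theta):
            """(−2 profiled loglik, beta_hat, info) at covariance params
            theta = (log sigma2, log-chol Sigma)."""
            sigma2 = np.exp(theta[0])
            L = np.zeros((d, d))
            iu = np.tril_indices(d)
            L[iu] = theta[1:]
            L[np.diag_indices(d)] = np.exp(np.diag(L))
            Sigma = L @ L.T
            A = np.zeros((p, p))
            b = np.zeros(p)
            logdet = 0.0
            blocks = []
            for Zp, Xp, yp in patterns:
                m = Zp.shape[0]
                V = Zp @ Sigma @ Zp.T + sigma2 * np.eye(m)
                cf = np.linalg.cholesky(V)
                Vi = np.linalg.inv(V)
                logdet += 2 * np.log(np.diag(cf)).sum() * Xp.shape[0]
                XtVi = np.einsum("smp,mk->skp", Xp, Vi)
                A += np.einsum("skp,skq->pq", XtVi, Xp)
                b += np.einsum("skp,sk->p", XtVi, yp)
                blocks.append((Xp, yp, Vi))
            beta = np.linalg.solve(A, b)
            quad = 0.0
            for Xp, yp, Vi in blocks:
                r = yp - Xp @ beta
                quad += np.einsum("sm,mk,sk->", r, Vi, r)
            m2ll = N * np.log(2 * np.pi) + logdet + quad
            return m2ll, beta, A

        def objective(theta):
            if np.abs(theta).max() > 40.0:  # keep exp() finite
                return 1e12
            try:
                with np.errstate(all="ignore"):
                    m2ll = profile(theta)[0]
            except np.linalg.LinAlgError:
                return 1e12
            return m2ll if np.isfinite(m2ll) else 1e12

        # multi-start: the profiled surface can have a spurious ridge
        # (inflated sigma2, singular Sigma) when many subjects carry a
        # single measurement, so try a moment-based start plus tight- and
        # loose-noise starts and keep the best optimum
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        sub_mean = pd.Series(resid).groupby(long["subject_id"].to_numpy()).mean()
        s2_total = max(float(resid.var()), 1e-6)
        s2_between = max(float(sub_mean.var()), 1e-4)
        s2_within = max(float(resid.var() - s2_between), 1e-4)
        starts = []
        for s2w in (s2_within, 1e-2 * s2_total, 0.5 * s2_total):
            theta0 = np.zeros(1 + d * (d + 1) // 2)
            theta0[0] = np.log(s2w)
            theta0[1] = 0.5 * np.log(s2_between)
            if d == 2:
                theta0[3] = 0.5 * np.log(max(s2_between / 4, 1e-4))
            starts.append(theta0)
        res = None
        for k, theta0 in enumerate(starts):
            if k == 0:
                cand = optimize.minimize(
                    objective, theta0, method="Nelder-Mead",
                    options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 400},
                )
                theta0 = cand.x
            cand = optimize.minimize(
                objective, theta0, method="BFGS",
                options={"gtol": 1e-8, "maxiter": 200},
            )
            if (
                res is None
                or not np.isfinite(res.fun)
                or (np.isfinite(cand.fun) and cand.fun < res.fun)
            ):
                res = cand
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            raise SingularFitError("marginal likelihood optimization failed")
        m2ll, beta, A = profile(res.x)
        sigma2 = float(np.exp(res.x[0]))
        L = np.zeros((d, d))
        L[np.tril_indices(d)] = res.x[1:]
        L[np.diag_indices(d)] = np.exp(np.diag(L))
        self.beta_ = beta
        self.Sigma_ = L @ L.T
        self.sigma2_ = sigma2
        self.se_beta_ = np.sqrt(np.diag(np.linalg.inv(A)))
        self.loglik_ = -0.5 * float(m2ll)
        self.converged_ = bool(res.success or np.isfinite(m2ll))

    def to_dict(self) -> dict:
        return {
            "beta1": dict(zip(self.param_names_, self.beta_.tolist())),
            "se_beta1": dict(zip(self.param_names_, self.se_beta_.tolist())),
            "Sigma": self.Sigma_.tolist(),
            "sigma2": self.sigma2_,
            "loglik": self.loglik_,
            "converged": self.converged_,
        }


def fit_lmm(study: StudyData, spec: LmmSpec = DEFAULT_SPEC) -> LinearMixedModel:
    """Functional wrapper over :class:`LinearMixedModel`."""
    return LinearMixedModel(spec).fit(study)


# ---------------------------------------------------------------------------
# exact marginal likelihood (oracle surface)
# ---------------------------------------------------------------------------

def _subject_blocks(study: StudyData, spec: LmmSpec):
    long = study.longitudinal
    X = spec.design(long)
    y = long["outcome"].to_numpy(dtype=float)
    Z = spec.random_design(long["time"].to_numpy())
    for _, idx in long.groupby("subject_id", sort=False).indices.items():
        yield X[idx], Z[idx], y[idx]


def lmm_marginal_loglik(
    beta: Sequence[float],
    Sigma: np.ndarray,
    sigma2: float,
    study: StudyData,
    spec: LmmSpec = DEFAULT_SPEC,
) -> float:
    """Exact Gaussian marginal log-likelihood of the mixed model.

    Marginalizes the random effects analytically:
    ``y_i ~ N(X_i beta, Z_i Sigma Z_i' + sigma2 I)``.  Raises on a
    non-positive-semidefinite ``Sigma`` or non-positive ``sigma2``.
    """
    beta = np.asarray(beta, dtype=float)
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if Sigma.shape != (spec.n_random, spec.n_random):
        raise ValueError("Sigma dimension inconsistent with random design")
    eig = np.linalg.eigvalsh((Sigma + Sigma.T) / 2)
    if eig.min() < -1e-10 * max(1.0, eig.max()):
        raise ValueError("Sigma must be positive semi-definite")

    total = 0.0
    for X, Z, y in _subject_blocks(study, spec):
        r = y - X @ beta
        V = Z @ Sigma @ Z.T + sigma2 * np.eye(len(y))
        L = np.linalg.cholesky(V)
        u = np.linalg.solve(L, r)
        total += -0.5 * (
            len(y) * np.log(2 * np.pi) + 2 * np.log(np.diag(L)).sum() + u @ u
        )
    return float(total)
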