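"""Shared random-effects joint model for longitudinal and survival outcomes.

Model (per study, subject i):

    longitudinal:  Y_ij = x_ij' beta1 + z(t_ij)' b_i + eps_ij
    hazard:        lambda_i(t) = lambda_0(t) exp(x_i' beta2 + alpha * z(t)' b_i)

with b_i ~ N(0, Sigma), eps ~ N(0, sigma2), and an unspecified baseline
hazard carrying mass only at observed event times.  The association is
"proportional": a single scalar ``alpha`` multiplies the zero-mean
random-effect component of the longitudinal trajectory, with the
longitudinal time variable replaced by event time inside the hazard.

Estimation is by EM (Wulfsohn–Tsiatis style):

* E-step — the posterior of ``b_i`` given the subject's full data is the
  Gaussian posterior from the longitudinal data alone, tilted by the
  survival likelihood.  Expectations are taken by adaptive Gauss–Hermite
  quadrature centered and scaled at that Gaussian posterior, so the
  quadrature weights reduce to (GH weight) x (survival likelihood at the
  node), and the observed-data log-likelihood is the exact Gaussian
  marginal plus a log quadrature sum.
* M-step — closed-form updates for beta1, sigma2, Sigma; a Breslow-type
  update for the baseline increments; a step-halved Newton update for
  (beta2, alpha) on the expected complete-data survival log-likelihood.

Standard errors are obtained by bootstrap resampling of subjects
(:func:`bootstrap_joint`), since profile-likelihood standard errors are
known to be underestimated when the baseline hazard is unspecified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cox import CoxFitError, CoxProportionalHazards
from .data import StudyData
from .lmm import DEFAULT_SPEC, LinearMixedModel, LmmSpec

logger = logging.getLogger(__name__)

try:  # numba accelerates the O(subjects x event-times x nodes) reductions
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is expected to be present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@dataclass(frozen=True)
class JointSpec:
    """Specification of the joint model: the longitudinal design plus the
    survival-submodel covariates.  The association structure is fixed to
    proportional shared zero-mean random effects."""

    lmm_spec: LmmSpec = DEFAULT_SPEC
    survival_covariates: tuple[str, ...] = ("treat",)


DEFAULT_JOINT_SPEC = JointSpec()


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _cumhaz_kernel(B0, B1, cut, t_e, lam0, alpha):
    """sum_{j < cut_i} lam0_j exp(alpha (B0_iq + B1_iq t_j)) for all i, q."""
    n, Q = B0.shape
    out = np.zeros((n, Q))
    for i in range(n):
        c = cut[i]
        for q in range(Q):
            a0 = alpha * B0[i, q]
            a1 = alpha * B1[i, q]
            s = 0.0
            for j in range(c):
                s += lam0[j] * np.exp(a0 + a1 * t_e[j])
            out[i, q] = s
    return out


@njit(cache=True, fastmath=True)
def _expcum_kernel(B0, B1, v, cut, t_e, lam0, alpha):
    """Per-subject expected cumulative hazard (without exp(eta)):
    sum_j lam0_j E_i[e^{alpha W_ij}]."""
    n, Q = B0.shape
    out = np.zeros(n)
    for i in range(n):
        c = cut[i]
        s0t = 0.0
        for j in range(c):
            s0 = 0.0
            for q in range(Q):
                s0 += v[i, q] * np.exp(alpha * (B0[i, q] + B1[i, q] * t_e[j]))
            s0t += lam0[j] * s0
        out[i] = s0t
    return out


@njit(cache=True, fastmath=True)
def _baseline_kernel(B0, B1, v, cut, t_e, alpha, expeta):
    """Breslow denominators S_j = sum_{i in R_j} e^{eta_i} E_i[e^{alpha W(t_j)}]."""
    n, Q = B0.shape
    m = t_e.shape[0]
    S = np.zeros(m)
    for i in range(n):
        c = cut[i]
        for j in range(c):
            s = 0.0
            for q in range(Q):
                s += v[i, q] * np.exp(alpha * (B0[i, q] + B1[i, q] * t_e[j]))
            S[j] += expeta[i] * s
    return S


@njit(cache=True, fastmath=True)
def _score_hess_kernel(B0, B1, v, cut, t_e, lam0, alpha, expeta, Xs):
    """Value, gradient and Hessian pieces of the expected survival
    log-likelihood in (beta2, alpha), at fixed baseline and posterior.

    Returns (cum, g_eta, g_alpha, h_aa) where for each subject i:
      cum[i]    = sum_j lam0_j E[e^{alpha W_ij}] * e^{eta_i}
      g_eta[i]  = same (coefficient of x_i in the beta2 gradient)
      g_alpha[i]= sum_j lam0_j E[W e^{alpha W}] e^{eta_i}
      h_aa[i]   = sum_j lam0_j E[W^2 e^{alpha W}] e^{eta_i}
    """
    n, Q = B0.shape
    cum = np.zeros(n)
    g_alpha = np.zeros(n)
    h_aa = np.zeros(n)
    for i in range(n):
        c = cut[i]
        s0t = 0.0
        s1t = 0.0
        s2t = 0.0
        for j in range(c):
            s0 = 0.0
            s1 = 0.0
            s2 = 0.0
            for q in range(Q):
                w = B0[i, q] + B1[i, q] * t_e[j]
                e = v[i, q] * np.exp(alpha * w)
                s0 += e
                s1 += w * e
                s2 += w * w * e
            s0t += lam0[j] * s0
            s1t += lam0[j] * s1
            s2t += lam0[j] * s2
        cum[i] = expeta[i] * s0t
        g_alpha[i] = expeta[i] * s1t
        h_aa[i] = expeta[i] * s2t
    return cum, g_alpha, h_aa


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def gauss_hermite_nodes(points: int, dim: int):
    """Product Gauss–Hermite rule: nodes (Q, dim) and probabilist-normalized
    weights summing to 1 (for expectations against a standard normal after
    the adaptive transform ``b = mu + sqrt(2) L u``)."""
    if points < 2:
        raise ValueError("quadrature order must be >= 2")
    x, w = np.polynomial.hermite.hermgauss(points)
    w = w / np.sqrt(np.pi)
    if dim == 1:
        return x[:, None], w
    xx = np.array(np.meshgrid(*([x] * dim), indexing="ij"))
    ww = np.ones([points] * dim)
    for d in range(dim):
        shape = [1] * dim
        shape[d] = points
        ww = ww * w.reshape(shape)
    return xx.reshape(dim, -1).T.copy(), ww.ravel()


def _chol2(C):
    """Cholesky factors of stacked 1x1 or 2x2 SPD matrices (n, d, d)."""
    n, d, _ = C.shape
    L = np.zeros_like(C)
    if d == 1:
        L[:, 0, 0] = np.sqrt(C[:, 0, 0])
    else:
        a = np.sqrt(C[:, 0, 0])
        L[:, 0, 0] = a
        L[:, 1, 0] = C[:, 1, 0] / a
        L[:, 1, 1] = np.sqrt(C[:, 1, 1] - L[:, 1, 0] ** 2)
    return L


def _inv2(A):
    """Inverses of stacked 1x1 or 2x2 matrices."""
    n, d, _ = A.shape
    out = np.empty_like(A)
    if d == 1:
        out[:, 0, 0] = 1.0 / A[:, 0, 0]
    else:
        det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
        out[:, 0, 0] = A[:, 1, 1] / det
        out[:, 1, 1] = A[:, 0, 0] / det
        out[:, 0, 1] = -A[:, 0, 1] / det
        out[:, 1, 0] = -A[:, 1, 0] / det
    return out


@dataclass
class _Prepared:
    """Study data reorganized for the EM loop."""

    X: np.ndarray          # (N, p1) longitudinal fixed design
    y: np.ndarray          # (N,)
    Z: np.ndarray          # (N, d) longitudinal random design
    row_subj: np.ndarray   # (N,) row -> subject index
    ZZ: np.ndarray         # (n, d, d) per-subject Z'Z
    n_obs: np.ndarray      # (n,) measurements per subject
    Xs: np.ndarray         # (n, p2) survival covariates
    T: np.ndarray          # (n,)
    delta: np.ndarray      # (n,)
    zT: np.ndarray         # (n, d) random design at the survival time
    t_e: np.ndarray        # (m,) distinct event times
    d_e: np.ndarray        # (m,) event counts
    cut: np.ndarray        # (n,) number of event times <= T_i
    ev_idx: np.ndarray     # (n,) index into t_e of own event time (-1 if censored)


def _prepare(study: StudyData, spec: JointSpec) -> _Prepared:
    long = study.longitudinal
    surv = study.survival.reset_index(drop=True)
    subj = surv["subject_id"]
    subj_pos = {s: k for k, s in enumerate(subj)}
    lspec = spec.lmm_spec
    X = lspec.design(long)
    y = long["outcome"].to_numpy(dtype=float)
    Z = lspec.random_design(long["time"].to_numpy())
    row_subj = long["subject_id"].map(subj_pos).to_numpy(dtype=np.int64)
    n, d = len(surv), lspec.n_random
    ZZ = np.zeros((n, d, d))
    np.add.at(ZZ, row_subj, Z[:, :, None] * Z[:, None, :])
    n_obs = np.bincount(row_subj, minlength=n).astype(float)
    T = surv["surv_time"].to_numpy(dtype=float)
    delta = surv["event"].to_numpy(dtype=int)
    if delta.sum() == 0:
        raise CoxFitError("no events observed")
    Xs = surv.loc[:, list(spec.survival_covariates)].to_numpy(dtype=float)
    zT = lspec.random_design(T)
    t_e, d_counts = np.unique(T[delta == 1], return_counts=True)
    cut = np.searchsorted(t_e, T, side="right").astype(np.int64)
    ev_idx = np.full(n, -1, dtype=np.int64)
    ev = delta == 1
    ev_idx[ev] = np.searchsorted(t_e, T[ev])
    return _Prepared(
        X, y, Z, row_subj, ZZ, n_obs, Xs, T, delta, zT,
        t_e, d_counts.astype(float), cut, ev_idx,
    )


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class SharedRandomEffectsJointModel(BaseEstimator):
    """EM-fitted joint model with proportional shared random effects.

    Parameters
    ----------
    spec : JointSpec
        Longitudinal design and survival covariates.
    quad_points : int
        Gauss–Hermite points per random-effect dimension (adaptive rule
        centered at each subject's longitudinal posterior).
    max_iter, tol : int, float
        EM stopping rule: max |relative parameter change| < tol.
    fix_alpha : float or None
        If set, the association parameter is held at this value (used for
        decoupling checks; ``fix_alpha=0`` reduces the fit to independent
        LMM + Cox maximum likelihood).

    Fitted attributes: ``beta1_``, ``beta2_``, ``alpha_``, ``Sigma_``,
    ``sigma2_``, ``baseline_``, ``loglik_``, ``loglik_trace_``, ``n_iter_``,
    ``converged_``.
    """

    def __init__(
        self,
        spec: JointSpec = DEFAULT_JOINT_SPEC,
        quad_points: int = 9,
        max_iter: int = 200,
        tol: float = 1e-5,
        inner_iter: int = 2,
        fix_alpha: float | None = None,
        accelerate: bool = True,
    ):
        self.spec = spec
        self.quad_points = quad_points
        self.max_iter = max_iter
        self.tol = tol
        self.inner_iter = inner_iter
        self.fix_alpha = fix_alpha
        self.accelerate = accelerate

    # -- internals ----------------------------------------------------
    def _estep(self, P: _Prepared, U, wq, beta1, beta2, alpha, Sigma, sigma2, lam0):
        """Posterior nodes/weights per subject + observed-data loglik."""
        n = len(P.T)
        d = U.shape[1]
        r = P.y - P.X @ beta1
        Zr = np.zeros((n, d))
        np.add.at(Zr, P.row_subj, P.Z * r[:, None])
        Sinv = np.linalg.inv(Sigma)
        Prec = P.ZZ / sigma2 + Sinv[None, :, :]
        C = _inv2(Prec)
        mu = np.einsum("nij,nj->ni", C, Zr) / sigma2
        L = _chol2(C)
        # nodes b_iq = mu_i + sqrt(2) L_i u_q  -> (n, Q, d)
        B = mu[:, None, :] + np.sqrt(2.0) * np.einsum("ndk,qk->nqd", L, U)
        B0 = np.ascontiguousarray(B[:, :, 0])
        B1 = (
            np.ascontiguousarray(B[:, :, 1])
            if d == 2
            else np.zeros_like(B0)
        )
        eta0 = P.Xs @ beta2
        expeta = np.exp(eta0)
        cumh = _cumhaz_kernel(B0, B1, P.cut, P.t_e, lam0, alpha)
        WT = B0 + B1 * P.T[:, None]
        logf = -expeta[:, None] * cumh
        ev = P.delta == 1
        loglam = np.zeros(n)
        loglam[ev] = np.log(lam0[P.ev_idx[ev]])
        logf[ev] += (loglam[ev] + eta0[ev])[:, None] + alpha * WT[ev]
        a = logf + np.log(wq)[None, :]
        amax = a.max(axis=1, keepdims=True)
        e = np.exp(a - amax)
        se = e.sum(axis=1)
        v = e / se[:, None]
        li_surv = amax[:, 0] + np.log(se)
        # exact Gaussian marginal of the longitudinal data (Woodbury)
        rss = np.zeros(n)
        np.add.at(rss, P.row_subj, r * r)
        quad = rss / sigma2 - np.einsum("ni,nij,nj->n", Zr, C, Zr) / sigma2**2
        if d == 2:
            logdet_prec = np.log(
                Prec[:, 0, 0] * Prec[:, 1, 1] - Prec[:, 0, 1] * Prec[:, 1, 0]
            )
            logdet_S = float(
                np.log(Sigma[0, 0] * Sigma[1, 1] - Sigma[0, 1] * Sigma[1, 0])
            )
        else:
            logdet_prec = np.log(Prec[:, 0, 0])
            logdet_S = float(np.log(Sigma[0, 0]))
        logdetV = P.n_obs * np.log(sigma2) + logdet_S + logdet_prec
        li_long = -0.5 * (P.n_obs * np.log(2 * np.pi) + logdetV + quad)
        loglik = float((li_long + li_surv).sum())
        Eb = np.einsum("nq,nqd->nd", v, B)
        Ebb = np.einsum("nq,nqd,nqe->nde", v, B, B)
        return B0, B1, v, Eb, Ebb, loglik, expeta

    def _surv_Q(self, P, B0, B1, v, cut, lam0, alpha, beta2, Eb):
        """Expected survival log-likelihood (without the fixed delta*log lam0
        term) used for Newton step halving."""
        eta0 = P.Xs @ beta2
        expeta = np.exp(eta0)
        cum = expeta * _expcum_kernel(B0, B1, v, cut, P.t_e, lam0, alpha)
        ev = P.delta == 1
        WTbar = (Eb[:, 0] + (Eb[:, 1] * P.T if Eb.shape[1] == 2 else 0.0))
        return float((eta0[ev] + alpha * WTbar[ev]).sum() - cum.sum())

    def fit(
        self,
        study: StudyData,
        init: dict | None = None,
    ) -> "SharedRandomEffectsJointModel":
        spec = self.spec
        P = _prepare(study, spec)
        d = spec.lmm_spec.n_random
        U, wq = gauss_hermite_nodes(self.quad_points, d)

        if init is None:
            lmm = LinearMixedModel(spec.lmm_spec).fit(study)
            cox = CoxProportionalHazards(spec.survival_covariates).fit(study)
            beta1 = lmm.beta_.copy()
            Sigma = np.atleast_2d(lmm.Sigma_).copy()
            sigma2 = max(lmm.sigma2_, 1e-10)
            beta2 = cox.beta_.copy()
            base = cox.baseline_
            lam0 = np.interp(P.t_e, base["time"], base["increment"])
            # exact when event-time grids coincide (they do on the same data)
            lam0 = np.maximum(lam0, 1e-12)
            alpha = 0.0
        else:
            beta1 = np.asarray(init["beta1"], dtype=float).copy()
            beta2 = np.asarray(init["beta2"], dtype=float).copy()
            alpha = float(init["alpha"])
            Sigma = np.atleast_2d(np.asarray(init["Sigma"], dtype=float)).copy()
            sigma2 = float(init["sigma2"])
            lam0 = np.interp(
                P.t_e, init["baseline"]["time"], init["baseline"]["increment"]
            )
            lam0 = np.maximum(lam0, 1e-12)
        if self.fix_alpha is not None:
            alpha = float(self.fix_alpha)

        XtX = P.X.T @ P.X
        p1, p2 = len(beta1), len(beta2)
        iu = np.triu_indices(d)

        def pack(beta1, beta2, alpha, sigma2, Sigma):
            return np.concatenate(
                [beta1, beta2, [alpha], [np.log(sigma2)], Sigma[iu]]
            )

        def unpack(x):
            beta1 = x[:p1]
            beta2 = x[p1 : p1 + p2]
            alpha = float(x[p1 + p2])
            sigma2 = float(np.exp(x[p1 + p2 + 1]))
            Sigma = np.zeros((d, d))
            Sigma[iu] = x[p1 + p2 + 2 :]
            Sigma = Sigma + np.triu(Sigma, 1).T
            return beta1, beta2, alpha, sigma2, Sigma

        def em_step(x, lam0):
            """One EM iteration from parameter vector x; returns the
            observed-data loglik AT x and the updated (x, lam0)."""
            beta1, beta2, alpha, sigma2, Sigma = unpack(x)
            B0, B1, v, Eb, Ebb, loglik, expeta = self._estep(
                P, U, wq, beta1, beta2, alpha, Sigma, sigma2, lam0
            )
            # closed-form longitudinal updates
            fit_rand = np.einsum("nd,nd->n", P.Z, Eb[P.row_subj])
            beta1 = np.linalg.solve(XtX, P.X.T @ (P.y - fit_rand))
            resid = P.y - P.X @ beta1 - fit_rand
            V = Ebb - Eb[:, :, None] * Eb[:, None, :]
            zVz = np.einsum("nd,nde,ne->n", P.Z, V[P.row_subj], P.Z)
            sigma2 = float((resid @ resid + zVz.sum()) / len(P.y))
            sigma2 = max(sigma2, 1e-12)
            Sigma = Ebb.mean(axis=0)
            Sigma = (Sigma + Sigma.T) / 2
            # numerical floor: keep Sigma strictly PD so the next E-step's
            # precision/Cholesky stay finite
            w_eig, V_eig = np.linalg.eigh(Sigma)
            if w_eig.min() < 1e-10:
                Sigma = (V_eig * np.clip(w_eig, 1e-10, None)) @ V_eig.T

            # survival updates: Breslow baseline + Newton for (beta2, alpha)
            ev = P.delta == 1
            WTbar = Eb[:, 0] + (Eb[:, 1] * P.T if d == 2 else 0.0)
            for _ in range(self.inner_iter):
                S = _baseline_kernel(B0, B1, v, P.cut, P.t_e, alpha, expeta)
                lam0 = P.d_e / np.maximum(S, 1e-300)
                cum, g_a, h_aa = _score_hess_kernel(
                    B0, B1, v, P.cut, P.t_e, lam0, alpha, expeta, P.Xs
                )
                score_b = P.Xs[ev].sum(axis=0) - P.Xs.T @ cum
                score_a = WTbar[ev].sum() - g_a.sum()
                H_bb = -(P.Xs * cum[:, None]).T @ P.Xs
                H_ba = -P.Xs.T @ g_a
                H_aa = -h_aa.sum()
                if self.fix_alpha is None:
                    grad = np.concatenate([score_b, [score_a]])
                    H = np.empty((p2 + 1, p2 + 1))
                    H[:p2, :p2] = H_bb
                    H[:p2, p2] = H_ba
                    H[p2, :p2] = H_ba
                    H[p2, p2] = H_aa
                else:
                    grad = score_b
                    H = H_bb
                try:
                    step = np.linalg.solve(H, grad)
                except np.linalg.LinAlgError:
                    step = grad / (np.abs(np.diag(H)).max() + 1e-8)
                if np.abs(step).max() < 1e-5:
                    # negligible move: ascent check not worth a kernel pass
                    if self.fix_alpha is None:
                        b2_new, a_new = beta2 - step[:-1], alpha - step[-1]
                    else:
                        b2_new, a_new = beta2 - step, alpha
                else:
                    eta0_cur = P.Xs @ beta2
                    Q0 = float(
                        (eta0_cur[ev] + alpha * WTbar[ev]).sum() - cum.sum()
                    )
                    for _ in range(25):
                        if self.fix_alpha is None:
                            b2_new = beta2 - step[:-1]
                            a_new = alpha - step[-1]
                        else:
                            b2_new = beta2 - step
                            a_new = alpha
                        Qn = self._surv_Q(
                            P, B0, B1, v, P.cut, lam0, a_new, b2_new, Eb
                        )
                        if Qn >= Q0 - 1e-10:
                            break
                        step = step / 2
                beta2, alpha = b2_new, a_new
                expeta = np.exp(P.Xs @ beta2)
            return loglik, pack(beta1, beta2, alpha, sigma2, Sigma), lam0

        # EM loop with guarded Aitken extrapolation: the slowest-converging
        # directions (Sigma vs alpha) have a near-geometric EM rate, so
        # every few plain steps we extrapolate along the step difference
        # and keep the jump only if the observed loglik did not decrease.
        x = pack(beta1, beta2, alpha, sigma2, Sigma)
        trace = []
        converged = False
        it = 0
        hist: list[np.ndarray] = [x]
        while it < self.max_iter:
            it += 1
            loglik, x_new, lam0_new = em_step(x, lam0)
            if not (np.isfinite(loglik) and np.isfinite(x_new).all()):
                # numerical breakdown: keep the last finite state, flagged
                logger.warning("joint EM hit non-finite values; stopping early")
                break
            trace.append(loglik)
            rel = np.abs(x_new - x) / (np.abs(x) + 1e-2)
            accepted_x, accepted_lam0 = x_new, lam0_new
            hist.append(x_new)
            if self.accelerate and len(hist) >= 3 and it % 2 == 0:
                d2 = hist[-1] - hist[-2]
                d1 = hist[-2] - hist[-3]
                denom = d1 @ d1
                r = (d2 @ d1) / denom if denom > 0 else 0.0
                if 0.0 < r < 1.0:
                    factor = min(r / (1.0 - r), 99.0)
                    x_acc = x_new + factor * d2
                    _, _, alpha_a, sigma2_a, Sigma_a = unpack(x_acc)
                    eig_ok = (
                        np.linalg.eigvalsh(Sigma_a).min() > 1e-10
                        and sigma2_a > 0
                    )
                    if eig_ok:
                        ll_acc, x_try, lam0_try = em_step(x_acc, lam0_new)
                        if ll_acc >= trace[-1] - 1e-7:
                            trace.append(ll_acc)
                            it += 1
                            accepted_x, accepted_lam0 = x_try, lam0_try
                            hist = [x_acc, x_try]
            x, lam0 = accepted_x, accepted_lam0
            if rel.max() < self.tol:
                converged = True
                break
        beta1, beta2, alpha, sigma2, Sigma = unpack(x)

        # final E-step for the loglik at the returned parameters
        *_, loglik, _ = self._estep(
            P, U, wq, beta1, beta2, alpha, Sigma, sigma2, lam0
        )
        trace.append(loglik)

        self.beta1_ = beta1
        self.beta2_ = beta2
        self.alpha_ = float(alpha)
        self.Sigma_ = Sigma
        self.sigma2_ = sigma2
        self.baseline_ = pd.DataFrame({"time": P.t_e, "increment": lam0})
        self.loglik_ = float(loglik)
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = it
        self.converged_ = converged
        self.param_names_ = (
            self.spec.lmm_spec.fixed_names,
            list(self.spec.survival_covariates),
        )
        if not converged:
            logger.info(
                "joint EM did not converge in %d iterations", self.max_iter
            )
        return self

    # -- serialization ------------------------------------------------
    def params_dict(self) -> dict:
        return {
            "beta1": self.beta1_.tolist(),
            "beta2": self.beta2_.tolist(),
            "alpha": self.alpha_,
            "Sigma": self.Sigma_.tolist(),
            "sigma2": self.sigma2_,
            "baseline": {
                "time": self.baseline_["time"].tolist(),
                "increment": self.baseline_["increment"].tolist(),
            },
            "loglik": self.loglik_,
            "n_iter": self.n_iter_,
            "converged": self.converged_,
        }


def fit_joint(
    study: StudyData,
    spec: JointSpec = DEFAULT_JOINT_SPEC,
    **control,
) -> SharedRandomEffectsJointModel:
    """Functional wrapper over :class:`SharedRandomEffectsJointModel`."""
    return SharedRandomEffectsJointModel(spec, **control).fit(study)


def joint_observed_loglik(
    params: dict,
    study: StudyData,
    spec: JointSpec = DEFAULT_JOINT_SPEC,
    quad_points: int = 9,
) -> float:
    """Numerically integrated observed-data log-likelihood at arbitrary
    parameters (an oracle surface for the EM ascent property).

    ``params`` requires keys ``beta1, beta2, alpha, Sigma, sigma2, baseline``
    where ``baseline`` holds ``time`` / ``increment`` lists; the baseline is
    re-gridded to the study's observed event times.
    """
    if quad_points < 2:
        raise ValueError("quadrature order must be >= 2")
    model = SharedRandomEffectsJointModel(spec, quad_points=quad_points)
    P = _prepare(study, spec)
    d = spec.lmm_spec.n_random
    U, wq = gauss_hermite_nodes(quad_points, d)
    lam0 = np.interp(
        P.t_e, params["baseline"]["time"], params["baseline"]["increment"]
    )
    lam0 = np.maximum(lam0, 1e-300)
    *_, loglik, _ = model._estep(
        P,
        U,
        wq,
        np.asarray(params["beta1"], dtype=float),
        np.asarray(params["beta2"], dtype=float),
        float(params["alpha"]),
        np.atleast_2d(np.asarray(params["Sigma"], dtype=float)),
        float(params["sigma2"]),
        lam0,
    )
    return loglik


# ---------------------------------------------------------------------------
# bootstrap standard errors
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Subject-resampling bootstrap of the joint model's parameters."""

    n_boot: int
    seed: int
    level: float
    param_names: list[str]
    replicate_estimates: np.ndarray  # (n_boot, n_params)
    se: dict[str, float] = field(init=False)
    ci: dict[str, tuple[float, float]] = field(init=False)
    estimates: dict[str, float] | None = None
    ci_method: str = "normal"
    n_redraws: int = 0

    def __post_init__(self):
        from scipy import stats

        sd = self.replicate_estimates.std(axis=0, ddof=1)
        self.se = dict(zip(self.param_names, sd.tolist()))
        z = stats.norm.ppf(0.5 + self.level / 2)
        ci = {}
        for k, name in enumerate(self.param_names):
            if self.ci_method == "percentile":
                lo, hi = np.quantile(
                    self.replicate_estimates[:, k],
                    [0.5 - self.level / 2, 0.5 + self.level / 2],
                )
            else:
                center = (
                    self.estimates[name]
                    if self.estimates
                    else self.replicate_estimates[:, k].mean()
                )
                lo, hi = center - z * sd[k], center + z * sd[k]
            ci[name] = (float(lo), float(hi))
        self.ci = ci


def _resample_study(study: StudyData, rng: np.random.Generator) -> StudyData:
    surv = study.survival.reset_index(drop=True)
    n = len(surv)
    pick = rng.integers(0, n, size=n)
    new_surv = surv.iloc[pick].reset_index(drop=True)
    groups = study.longitudinal.groupby("subject_id", sort=False).indices
    rows = []
    ids = []
    for new_id, (k, old_id) in enumerate(zip(pick, new_surv["subject_id"])):
        idx = groups.get(old_id)
        if idx is not None:
            rows.append(idx)
            ids.extend([new_id] * len(idx))
    long = study.longitudinal.iloc[np.concatenate(rows)].copy()
    long["subject_id"] = ids
    new_surv = new_surv.copy()
    new_surv["subject_id"] = np.arange(n)
    return StudyData(study.study_id, long.reset_index(drop=True), new_surv)


def bootstrap_joint(
    study: StudyData,
    spec: JointSpec = DEFAULT_JOINT_SPEC,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
    ci_method: str = "normal",
    fitted: SharedRandomEffectsJointModel | None = None,
    quad_points: int = 9,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> BootstrapResult:
    """Bootstrap SEs/CIs for the joint fit by resampling subjects.

    Replicates are refit warm-started from the full-data fit.  A replicate
    with zero events is redrawn (logged); more than 50% redraws raises.
    Deterministic given ``seed`` — replicate r uses the substream keyed by
    (seed, r), independent of execution order.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if fitted is None:
        fitted = SharedRandomEffectsJointModel(spec, quad_points=quad_points).fit(study)
    init = fitted.params_dict()
    names = (
        [f"beta1_{n}" for n in spec.lmm_spec.fixed_names]
        + [f"beta2_{n}" for n in spec.survival_covariates]
        + ["alpha"]
    )
    est = dict(
        zip(
            names,
            np.concatenate(
                [fitted.beta1_, fitted.beta2_, [fitted.alpha_]]
            ).tolist(),
        )
    )
    reps = np.empty((n_boot, len(names)))
    n_redraws = 0
    for r in range(n_boot):
        for attempt in range(1000):
            rng = np.random.default_rng([seed, r, attempt])
            bs = _resample_study(study, rng)
            if bs.survival["event"].sum() > 0:
                break
            n_redraws += 1
            if n_redraws > n_boot / 2:
                raise RuntimeError("more than 50% of bootstrap replicates redrawn")
        m = SharedRandomEffectsJointModel(
            spec, quad_points=quad_points, max_iter=max_iter, tol=tol
        ).fit(bs, init=init)
        reps[r] = np.concatenate([m.beta1_, m.beta2_, [m.alpha_]])
    if n_redraws:
        logger.info("bootstrap redrew %d zero-event replicates", n_redraws)
    return BootstrapResult(
        n_boot=n_boot,
        seed=seed,
        level=level,
        param_names=names,
        replicate_estimates=reps,
        estimates=est,
        ci_method=ci_method,
        n_redraws=n_redraws,
    )
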