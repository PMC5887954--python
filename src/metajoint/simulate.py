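"""Multi-study joint-data generator with Gompertz event times.

Each scenario generates K studies of n subjects randomized 1:1 to two
arms.  The longitudinal outcome follows the linear mixed model

    Y_ij = beta10 + beta11 t + beta12 treat + b0_i + b1_i t + eps_ij

on a fixed visit grid (default 0..4), with records kept only strictly
before the subject's survival time.  Event times are Gompertz with
scale exp(theta0 + alpha b0) and shape theta1 + alpha b1 — the same
shared random effects scaled by the association parameter alpha — and a
proportional treatment effect on the hazard.  When the realized shape is
negative the Gompertz is defective: with the matching probability the
subject never experiences the event (infinite event time, a cure
fraction).  Censoring is exponential; the observed time is the minimum
of event and censoring times.

The baseline (theta0, theta1) pair is calibrated by moment matching so
that the reference-arm, zero-random-effect event time has a prescribed
mean and standard deviation (default mean 3, SD 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .data import MetaDataset, StudyData

HIGH_EVENT_RATE_LAMBDA = float(np.exp(-3.08))
LOW_EVENT_RATE_LAMBDA = float(np.exp(-0.58))


# ---------------------------------------------------------------------------
# Gompertz calibration
# ---------------------------------------------------------------------------

def gompertz_survival(t, theta0: float, theta1: float):
    """Survivor function S(t) = exp((e^theta0 / theta1)(1 - e^{theta1 t})),
    with the exponential limit at theta1 = 0."""
    t = np.asarray(t, dtype=float)
    if theta1 == 0.0:
        return np.exp(-np.exp(theta0) * t)
    with np.errstate(over="ignore"):  # overflow -> S(t) = 0, intended
        return np.exp(-(np.exp(theta0) / theta1) * np.expm1(theta1 * t))


def gompertz_moments(theta0: float, theta1: float) -> tuple[float, float]:
    """(mean, SD) of the Gompertz by numerical integration of the survivor
    function: E[T] = int S, E[T^2] = int 2 t S."""
    m1, _ = integrate.quad(lambda t: gompertz_survival(t, theta0, theta1), 0, np.inf)
    m2, _ = integrate.quad(
        lambda t: 2 * t * gompertz_survival(t, theta0, theta1), 0, np.inf
    )
    var = m2 - m1**2
    return float(m1), float(np.sqrt(max(var, 0.0)))


class CalibrationError(RuntimeError):
    pass


def calibrate_gompertz(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Moment-match (theta0, theta1) to a target event-time mean and SD.

    Uses the scale-family structure of the Gompertz: with rho =
    e^theta0/theta1, the distribution of theta1*T depends on rho alone, so
    the coefficient of variation pins rho (1-D root find) and the mean then
    fixes theta1.  The coefficient of variation of a (proper, increasing-
    hazard) Gompertz lies in (0, 1], with the exponential limit at 1;
    targets outside that range are not attainable.
    """
    if target_mean <= 0 or target_sd <= 0:
        raise CalibrationError("targets must be positive")
    cv = target_sd / target_mean
    if cv >= 1.0:
        if np.isclose(cv, 1.0):
            return (-float(np.log(target_mean)), 0.0)
        raise CalibrationError("no solution bracketed: Gompertz needs SD < mean")

    def std_moments(log_rho):
        rho = np.exp(log_rho)

        def S(s):
            with np.errstate(over="ignore"):
                return np.exp(-rho * np.expm1(s))

        m1, _ = integrate.quad(S, 0, np.inf)
        m2, _ = integrate.quad(lambda s: 2 * s * S(s), 0, np.inf)
        return m1, np.sqrt(max(m2 - m1**2, 0.0))

    def cv_gap(log_rho):
        m1, sd = std_moments(log_rho)
        return sd / m1 - cv

    try:
        # cv is monotone in rho, approaching 0 as rho -> 0 and 1 (the
        # exponential limit) as rho -> inf; this bracket covers cv in
        # (~1e-2, 0.997)
        log_rho = optimize.brentq(cv_gap, -60.0, 8.0, xtol=1e-13)
    except ValueError as exc:  # pragma: no cover - defensive
        raise CalibrationError("no solution bracketed") from exc
    m1, _ = std_moments(log_rho)
    theta1 = m1 / target_mean
    theta0 = float(log_rho + np.log(theta1))
    return theta0, float(theta1)


# ---------------------------------------------------------------------------
# elementary draws
# ---------------------------------------------------------------------------

def draw_event_time(
    b0: float,
    b1: float,
    alpha: float,
    theta0: float,
    theta1: float,
    beta21: float,
    treat: float,
    U: float,
) -> float:
    """Inverse-transform Gompertz event time with shared-random-effect
    shift of scale and shape, or +inf on the defective (cure) branch.

    The subject-level shape is theta1 + alpha*b1 and log-scale
    theta0 + alpha*b0; the hazard is multiplied by exp(beta21 * treat).
    If the shape is negative, the total hazard is finite and with
    probability exp(scale/shape) (evaluated without the treatment term,
    then compared against U) the event never occurs.
    """
    if not 0.0 < U < 1.0:
        raise ValueError("U must lie strictly in (0, 1)")
    shape = theta1 + alpha * b1
    scale = np.exp(theta0 + alpha * b0)
    if shape < 0 and U < np.exp(scale / shape):
        return float("inf")
    num = -shape * np.log(U) / (scale * np.exp(beta21 * treat))
    arg = 1.0 + num
    if shape == 0.0:
        return float(-np.log(U) / (scale * np.exp(beta21 * treat)))
    assert arg > 0.0, "inverse-transform argument must be positive off the cure branch"
    return float(np.log(arg) / shape)


def _draw_event_times_vec(b0, b1, alpha, theta0, theta1, beta21, treat, U):
    shape = theta1 + alpha * b1
    scale = np.exp(theta0 + alpha * b0)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        cure = (shape < 0) & (U < np.exp(scale / shape))
        haz = scale * np.exp(beta21 * treat)
        arg = 1.0 - shape * np.log(U) / haz
        T = np.where(
            np.abs(shape) < 1e-300,
            -np.log(U) / haz,
            np.log(np.maximum(arg, 1e-300)) / np.where(shape == 0, 1.0, shape),
        )
    T = np.where(cure, np.inf, T)
    assert np.all(cure | (arg > 0)), "inverse transform argument non-positive"
    return T


def draw_censoring_time(U, lambda_cens: float):
    """Exponential censoring time -log(U)/lambda."""
    if lambda_cens <= 0:
        raise ValueError("lambda_cens must be positive")
    U = np.asarray(U, dtype=float)
    if np.any((U <= 0) | (U >= 1)):
        raise ValueError("U must lie strictly in (0, 1)")
    out = -np.log(U) / lambda_cens
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """Full generative specification of one simulation scenario.

    Defaults reproduce the reference study conditions: 5 studies of 500
    subjects, visits at 0..4 capped strictly below the survival time,
    Gompertz events calibrated to mean 3 / SD 1, exponential censoring
    with rate exp(-3.08) ("high" event-rate regime) or exp(-0.58)
    ("low"), longitudinal fixed effects (1, 3, 2), survival treatment
    log-hazard 3, random-effect covariance [[0.9, 0.5], [0.5, 1.2]],
    residual variance 0.01.  Heterogeneous scenarios draw per-study
    treatment effects from N(beta12, het_spread) and N(beta21,
    het_spread) with ``het_spread`` read as a variance.
    """

    K: int = 5
    n_per_study: int = 500
    meas_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    alpha: float = 0.0
    beta10: float = 1.0
    beta11: float = 3.0
    beta12: float = 2.0
    beta21: float = 3.0
    Sigma: tuple[tuple[float, float], ...] = ((0.9, 0.5), (0.5, 1.2))
    sigma2_eps: float = 0.01
    theta0: float | None = None
    theta1: float | None = None
    gompertz_mean: float = 3.0
    gompertz_sd: float = 1.0
    lambda_cens: float = HIGH_EVENT_RATE_LAMBDA
    heterogeneous: bool = False
    het_spread: float = 0.5
    seed: int = 0

    def __post_init__(self):
        S = np.asarray(self.Sigma, dtype=float)
        if np.linalg.eigvalsh((S + S.T) / 2).min() < 0:
            raise ValueError("Sigma must be positive semi-definite")
        if self.lambda_cens <= 0:
            raise ValueError("lambda_cens must be positive")
        if self.n_per_study % 2:
            raise ValueError("n_per_study must be even (1:1 randomization)")

    def with_calibration(self) -> "ScenarioConfig":
        """Return a copy with (theta0, theta1) filled in by moment matching."""
        if self.theta0 is not None and self.theta1 is not None:
            return self
        th0, th1 = calibrate_gompertz(self.gompertz_mean, self.gompertz_sd)
        return replace(self, theta0=th0, theta1=th1)

    @property
    def Sigma_array(self) -> np.ndarray:
        return np.asarray(self.Sigma, dtype=float)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


# ---------------------------------------------------------------------------
# study and meta-dataset generation
# ---------------------------------------------------------------------------

def simulate_study(
    config: ScenarioConfig,
    study_index: int = 0,
    per_study_effects: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[StudyData, pd.DataFrame]:
    """Generate one study; returns (StudyData, per-subject truth table).

    ``per_study_effects`` is the realized (beta12_k, beta21_k) pair; by
    default the homogeneous values from the config are used.  The truth
    table records the latent random effects and the uncensored event and
    censoring times.
    """
    config = config.with_calibration()
    if rng is None:
        rng = np.random.default_rng([config.seed, study_index])
    beta12_k, beta21_k = per_study_effects or (config.beta12, config.beta21)
    n = config.n_per_study
    treat = rng.permutation(np.repeat([0.0, 1.0], n // 2))
    # eigen-factor handles singular (PSD) covariances, e.g. Sigma = 0
    w, V = np.linalg.eigh(config.Sigma_array)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    b = rng.standard_normal((n, 2)) @ L.T
    U_event = rng.uniform(size=n)
    U_cens = rng.uniform(size=n)
    TE = _draw_event_times_vec(
        b[:, 0], b[:, 1], config.alpha, config.theta0, config.theta1,
        beta21_k, treat, U_event,
    )
    TC = draw_censoring_time(U_cens, config.lambda_cens)
    T = np.minimum(TE, TC)
    event = (TE <= TC).astype(int)

    times = np.asarray(config.meas_times, dtype=float)
    keep = times[None, :] < T[:, None]
    subj = np.repeat(np.arange(n), keep.sum(axis=1))
    tt = np.broadcast_to(times, (n, times.size))[keep]
    eps = rng.normal(0.0, np.sqrt(config.sigma2_eps), size=tt.size)
    y = (
        config.beta10
        + config.beta11 * tt
        + beta12_k * treat[subj]
        + b[subj, 0]
        + b[subj, 1] * tt
        + eps
    )
    study_id = f"study{study_index}"
    long = pd.DataFrame(
        {"subject_id": subj, "time": tt, "outcome": y, "treat": treat[subj]}
    )
    surv = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "surv_time": T,
            "event": event,
            "treat": treat,
        }
    )
    truth = pd.DataFrame(
        {
            "study_id": study_id,
            "subject_id": np.arange(n),
            "b0": b[:, 0],
            "b1": b[:, 1],
            "T_event": TE,
            "T_cens": TC,
            "beta12_k": beta12_k,
            "beta21_k": beta21_k,
        }
    )
    return StudyData(study_id, long, surv), truth


def simulate_meta_dataset(
    config: ScenarioConfig,
) -> tuple[MetaDataset, pd.DataFrame]:
    """Generate K studies; heterogeneous scenarios draw per-study treatment
    effects from N(beta12, het_spread) / N(beta21, het_spread) (variance
    parameterization).  Fully reproducible from ``config.seed``."""
    config = config.with_calibration()
    rng_eff = np.random.default_rng([config.seed, 987654321])
    studies, truths = [], []
    for k in range(config.K):
        if config.heterogeneous:
            eff = (
                float(rng_eff.normal(config.beta12, np.sqrt(config.het_spread))),
                float(rng_eff.normal(config.beta21, np.sqrt(config.het_spread))),
            )
        else:
            eff = (config.beta12, config.beta21)
        s, t = simulate_study(config, k, per_study_effects=eff)
        studies.append(s)
        truths.append(t)
    return MetaDataset(studies), pd.concat(truths, ignore_index=True)
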