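import numpy as np
import pytest

from metajoint import (
    SharedRandomEffectsJointModel,
    StudyData,
    bootstrap_joint,
    fit_cox,
    fit_joint,
    fit_lmm,
    joint_observed_loglik,
    lmm_marginal_loglik,
    simulate_study,
)
from metajoint.cox import CoxFitError
from tests.conftest import small_config

QP = 5  # Gauss-Hermite points per dimension for unit tests


class TestDecoupling:
    def test_alpha_fixed_at_zero_reproduces_separate_fits(self, null_assoc_study):
        """With the association frozen at 0 the joint likelihood factorizes,
        so the EM must land on the separate LMM + Cox maximum likelihood."""
        study, _ = null_assoc_study
        lmm = fit_lmm(study)
        cox = fit_cox(study)
        jm = SharedRandomEffectsJointModel(quad_points=QP, fix_alpha=0.0).fit(study)
        assert np.abs(jm.beta1_ - lmm.beta_).max() < 1e-3
        assert abs(jm.sigma2_ - lmm.sigma2_) < 1e-3
        assert np.abs(jm.Sigma_ - lmm.Sigma_).max() < 1e-3
        assert np.abs(jm.beta2_ - cox.beta_).max() < 1e-2

    def test_free_alpha_near_zero_on_null_data(self, null_assoc_study):
        study, _ = null_assoc_study
        jm = SharedRandomEffectsJointModel(quad_points=QP).fit(study)
        assert abs(jm.alpha_) < 0.15


class TestEmAscent:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_loglik_trace_monotone(self, alpha):
        study, _ = simulate_study(small_config(alpha=alpha, seed=17), 0)
        jm = SharedRandomEffectsJointModel(quad_points=QP).fit(study)
        diffs = np.diff(jm.loglik_trace_)
        assert diffs.min() > -1e-6

    def test_fitted_loglik_beats_initializer(self, assoc_study):
        study, _ = assoc_study
        lmm = fit_lmm(study)
        cox = fit_cox(study)
        init_params = {
            "beta1": lmm.beta_,
            "beta2": cox.beta_,
            "alpha": 0.0,
            "Sigma": lmm.Sigma_,
            "sigma2": lmm.sigma2_,
            "baseline": {
                "time": cox.baseline_["time"].tolist(),
                "increment": cox.baseline_["increment"].tolist(),
            },
        }
        jm = SharedRandomEffectsJointModel(quad_points=QP).fit(study)
        ll_init = joint_observed_loglik(init_params, study, quad_points=QP)
        assert jm.loglik_ >= ll_init


class TestObservedLoglik:
    def test_additive_decomposition_at_alpha_zero(self, null_assoc_study):
        """At alpha = 0 the joint likelihood is the exact Gaussian marginal
        plus the full survival likelihood with plugged-in baseline."""
        study, _ = null_assoc_study
        lmm = fit_lmm(study)
        cox = fit_cox(study)
        params = {
            "beta1": lmm.beta_,
            "beta2": cox.beta_,
            "alpha": 0.0,
            "Sigma": lmm.Sigma_,
            "sigma2": lmm.sigma2_,
            "baseline": {
                "time": cox.baseline_["time"].tolist(),
                "increment": cox.baseline_["increment"].tolist(),
            },
        }
        ll = joint_observed_loglik(params, study, quad_points=QP)
        ll_long = lmm_marginal_loglik(lmm.beta_, lmm.Sigma_, lmm.sigma2_, study)
        # hand-written survival full likelihood at the Breslow baseline
        surv = study.survival
        T = surv["surv_time"].to_numpy()
        delta = surv["event"].to_numpy()
        eta = surv["treat"].to_numpy() * cox.beta_[0]
        te = cox.baseline_["time"].to_numpy()
        lam = cox.baseline_["increment"].to_numpy()
        cumlam = np.concatenate([[0.0], np.cumsum(lam)])
        H = cumlam[np.searchsorted(te, T, side="right")]
        ev = delta == 1
        ll_surv = (
            np.log(lam[np.searchsorted(te, T[ev])]).sum()
            + eta[ev].sum()
            - (np.exp(eta) * H).sum()
        )
        assert ll == pytest.approx(ll_long + ll_surv, abs=1e-6)

    def test_quadrature_refinement_converged(self):
        study, _ = simulate_study(
            small_config(alpha=0.5, n_per_study=50, seed=91), 0
        )
        jm = SharedRandomEffectsJointModel(quad_points=QP).fit(study)
        params = jm.params_dict()
        ll1 = joint_observed_loglik(params, study, quad_points=9)
        ll2 = joint_observed_loglik(params, study, quad_points=18)
        assert abs(ll1 - ll2) < 1e-4

    def test_quadrature_order_below_two_rejected(self, null_assoc_study):
        study, _ = null_assoc_study
        with pytest.raises(ValueError):
            joint_observed_loglik({}, study, quad_points=1)


class TestAssociationRecovery:
    def test_alpha_estimate_tracks_generating_value(self, assoc_study):
        study, _ = assoc_study
        jm = SharedRandomEffectsJointModel(quad_points=QP).fit(study)
        # single small study: generous bound, tightened by the pooled
        # acceptance checks at full scale
        assert jm.alpha_ == pytest.approx(0.5, abs=0.25)

    def test_sign_equivariance_under_outcome_negation(self, assoc_study):
        """Negating the longitudinal outcome flips the random-effect
        parameterization, so the association estimate flips sign and the
        survival treatment effect is unchanged."""
        study, _ = assoc_study
        jm = SharedRandomEffectsJointModel(quad_points=QP).fit(study)
        neg = StudyData(
            "neg",
            study.longitudinal.assign(outcome=lambda d: -d["outcome"]),
            study.survival,
        )
        jn = SharedRandomEffectsJointModel(quad_points=QP).fit(neg)
        assert jn.alpha_ == pytest.approx(-jm.alpha_, abs=1e-4)
        assert np.allclose(jn.beta1_, -jm.beta1_, atol=1e-4)
        assert np.allclose(jn.beta2_, jm.beta2_, atol=1e-4)
        assert jn.loglik_ == pytest.approx(jm.loglik_, abs=1e-6)

    def test_zero_events_rejected(self):
        study, _ = simulate_study(small_config(n_per_study=10, seed=2), 0)
        censored = StudyData(
            "cens",
            study.longitudinal,
            study.survival.assign(event=0),
        )
        with pytest.raises(CoxFitError):
            fit_joint(censored, quad_points=QP)


class TestBootstrap:
    def test_same_seed_identical_results(self, assoc_study):
        study, _ = assoc_study
        fitted = SharedRandomEffectsJointModel(quad_points=3).fit(study)
        kw = dict(n_boot=4, seed=5, fitted=fitted, quad_points=3, max_iter=15)
        b1 = bootstrap_joint(study, **kw)
        b2 = bootstrap_joint(study, **kw)
        assert np.array_equal(b1.replicate_estimates, b2.replicate_estimates)
        assert b1.se == b2.se

    def test_single_replicate_rejected(self, assoc_study):
        study, _ = assoc_study
        with pytest.raises(ValueError):
            bootstrap_joint(study, n_boot=1, seed=0)

    def test_se_positive_and_ci_ordered(self, assoc_study):
        study, _ = assoc_study
        fitted = SharedRandomEffectsJointModel(quad_points=3).fit(study)
        b = bootstrap_joint(
            study, n_boot=6, seed=3, fitted=fitted, quad_points=3, max_iter=15
        )
        for name in b.param_names:
            assert b.se[name] > 0
            lo, hi = b.ci[name]
            assert lo < hi

    def test_percentile_interval_option(self, assoc_study):
        study, _ = assoc_study
        fitted = SharedRandomEffectsJointModel(quad_points=3).fit(study)
        b = bootstrap_joint(
            study, n_boot=6, seed=3, fitted=fitted, quad_points=3,
            max_iter=15, ci_method="percentile",
        )
        lo, hi = b.ci["alpha"]
        reps = b.replicate_estimates[:, b.param_names.index("alpha")]
        assert lo >= reps.min() and hi <= reps.max()


def test_bootstrap_se_tracks_monte_carlo_sd():
    """Bootstrap SE of the association estimate agrees with the empirical
    SD of the estimate across independent generator replicates (within
    50%, at deliberately small problem sizes)."""
    cfg = small_config(alpha=0.5, n_per_study=60, seed=71)
    study, _ = simulate_study(cfg, 0)
    fitted = SharedRandomEffectsJointModel(quad_points=3).fit(study)
    boot = bootstrap_joint(
        study, n_boot=40, seed=9, fitted=fitted, quad_points=3,
        max_iter=25, tol=1e-3,
    )
    ests = []
    for r in range(40):
        s, _ = simulate_study(small_config(alpha=0.5, n_per_study=60, seed=9000 + r), 0)
        try:
            ests.append(
                SharedRandomEffectsJointModel(
                    quad_points=3, max_iter=60, tol=1e-4
                ).fit(s).alpha_
            )
        except Exception:
            continue
    mc_sd = np.std(ests, ddof=1)
    assert 0.5 * mc_sd < boot.se["alpha"] < 2.0 * mc_sd
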