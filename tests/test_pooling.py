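import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metajoint import (
    EffectEstimate,
    MetaAnalysis,
    ci_to_se,
    dl_heterogeneity,
    forest_table,
    pool_fixed,
    pool_grouped,
    pool_random,
)
from metajoint.datasets import STUDY_COUNTS_DEATH, indana_effects
from metajoint.pooling import effects_from_frame
import pandas as pd


def _effects(pairs, parameter="b", group=None):
    return [
        EffectEstimate(f"s{i}", parameter, est, var, group=group)
        for i, (est, var) in enumerate(pairs)
    ]


class TestCiToSe:
    def test_printed_interval(self):
        assert ci_to_se(-13.11, -8.69, 0.95) == pytest.approx(1.1276, abs=1e-4)

    def test_unit_width_normalization(self):
        z = stats.norm.ppf(0.975)
        assert ci_to_se(-z, z, 0.95) == pytest.approx(1.0, rel=1e-12)

    def test_lower_level_implies_larger_se(self):
        assert ci_to_se(0.0, 1.0, 0.5) > ci_to_se(0.0, 1.0, 0.95)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            ci_to_se(1.0, 1.0)


class TestPublishedHypertensionRows:
    """Published aggregate rows for systolic blood pressure re-pooled."""

    def test_death_longitudinal_fixed_and_random(self):
        ests = indana_effects("death", "beta12", "separate")
        fixed = pool_fixed(ests)
        random = pool_random(ests)
        assert fixed.pooled == pytest.approx(-8.66, abs=0.01)
        assert random.pooled == pytest.approx(-9.86, abs=0.01)

    def test_death_longitudinal_heterogeneity(self):
        Q, tau2, I2, p = dl_heterogeneity(
            indana_effects("death", "beta12", "separate")
        )
        assert tau2 == pytest.approx(3.2091, abs=0.01)
        assert 100 * I2 == pytest.approx(95.20, abs=0.2)
        assert p < 1e-4

    def test_stroke_survival_fixed_with_no_heterogeneity(self):
        ests = indana_effects("stroke", "beta21", "separate")
        fixed = pool_fixed(ests)
        Q, tau2, I2, _ = dl_heterogeneity(ests)
        assert fixed.pooled == pytest.approx(-0.46, abs=0.005)
        assert Q < len(ests) - 1
        assert tau2 == 0.0
        assert I2 == 0.0

    def test_study_counts_recorded(self):
        n, ev, meas = STUDY_COUNTS_DEATH["COOP"]
        assert (n, ev, meas) == (884, 130, 4621)


class TestPoolFixed:
    def test_single_study_identity(self):
        e = EffectEstimate("s", "b", 1.5, 0.04)
        res = pool_fixed([e])
        assert res.pooled == 1.5
        z = stats.norm.ppf(0.975)
        assert res.ci == pytest.approx((1.5 - z * 0.2, 1.5 + z * 0.2))

    def test_equal_variances_average(self):
        res = pool_fixed(_effects([(1.0, 0.5), (3.0, 0.5)]))
        assert res.pooled == pytest.approx(2.0)

    def test_mixed_parameters_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed(
                [EffectEstimate("a", "x", 1, 1), EffectEstimate("b", "y", 2, 1)]
            )


class TestDLHeterogeneity:
    def test_hand_computed_two_study_example(self):
        """theta = 0 +- 1 and 2 +- 1: w=1 each, fixed=1, Q=2, df=1,
        denominator = 2 - 2/2 = 1, tau2 = (2-1)/1 = 1, I2 = 1/2."""
        Q, tau2, I2, p = dl_heterogeneity(_effects([(0.0, 1.0), (2.0, 1.0)]))
        assert Q == pytest.approx(2.0)
        assert tau2 == pytest.approx(1.0)
        assert I2 == pytest.approx(0.5)
        assert p == pytest.approx(stats.chi2.sf(2.0, 1), rel=1e-12)

    def test_identical_estimates_give_zero_heterogeneity(self):
        Q, tau2, I2, _ = dl_heterogeneity(_effects([(1.0, 0.3)] * 4))
        assert (Q, tau2, I2) == (0.0, 0.0, 0.0)

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            dl_heterogeneity(_effects([(1.0, 1.0)]))


class TestPoolRandom:
    def test_reduces_to_fixed_when_tau2_zero(self):
        ests = _effects([(1.0, 0.3)] * 3)
        f, r = pool_fixed(ests), pool_random(ests)
        assert r.pooled == pytest.approx(f.pooled)
        assert r.se == pytest.approx(f.se)

    def test_large_tau2_limit_approaches_plain_mean(self):
        # wildly different variances but huge spread in estimates
        ests = _effects([(0.0, 1e-6), (10.0, 1e-2), (20.0, 1e-4)])
        res = pool_random(ests)
        assert res.pooled == pytest.approx(np.mean([0.0, 10.0, 20.0]), rel=0.01)

    def test_weights_use_tau2(self):
        ests = _effects([(0.0, 1.0), (2.0, 1.0)])
        res = pool_random(ests)
        # tau2 = 1 -> weights 1/(1+1); se = sqrt(1 / (2 * 0.5)) = 1
        assert res.se == pytest.approx(1.0)


class TestPoolGrouped:
    def test_partition_property(self):
        ests = _effects([(1.0, 0.5), (1.5, 0.5), (2.0, 0.5)], group="g1")
        ests += _effects([(5.0, 0.2), (5.5, 0.2), (6.0, 0.2)], group="g2")
        out = pool_grouped(ests)
        only_g1 = [e for e in ests if e.group == "g1"]
        assert out["g1"]["fixed"].pooled == pytest.approx(
            pool_fixed(only_g1).pooled
        )
        assert set(out) == {"g1", "g2"}

    def test_single_group_matches_ungrouped(self):
        ests = _effects([(1.0, 0.5), (2.0, 0.4)], group="only")
        out = pool_grouped(ests)
        assert out["only"]["random"].pooled == pytest.approx(
            pool_random([e for e in ests]).pooled
        )

    def test_singleton_group_has_no_random_result(self):
        ests = _effects([(1.0, 0.5)], group="lonely")
        out = pool_grouped(ests)
        assert out["lonely"]["fixed"].pooled == 1.0
        assert out["lonely"]["random"] is None

    def test_missing_group_label_rejected(self):
        with pytest.raises(ValueError):
            pool_grouped(_effects([(1.0, 0.5)]))


class TestForestTable:
    def test_row_structure(self):
        ests = indana_effects("death", "beta12", "separate")
        t = forest_table(ests, pool_fixed(ests), pool_random(ests))
        assert (t["row_type"] == "study").sum() == 6
        assert set(t["row_type"]) == {
            "study", "pooled_fixed", "pooled_random", "heterogeneity",
        }

    def test_single_study(self):
        ests = [EffectEstimate("s", "b", 1.0, 0.1)]
        t = forest_table(ests, pool_fixed(ests), None)
        assert len(t) == 3  # study + fixed summary + heterogeneity footer

    def test_weights_sum_to_100(self):
        ests = _effects([(1.0, 0.5), (2.0, 0.3), (0.5, 0.9)])
        t = forest_table(ests, pool_fixed(ests), pool_random(ests))
        studies = t[t["row_type"] == "study"]
        assert studies["weight_fixed_pct"].sum() == pytest.approx(100.0)
        assert studies["weight_random_pct"].sum() == pytest.approx(100.0)


class TestCsvInterchange:
    def test_se_and_ci_inputs_equivalent(self):
        df_se = pd.DataFrame(
            {"study_id": ["a"], "parameter": ["b"], "estimate": [1.0], "se": [0.5]}
        )
        z = stats.norm.ppf(0.975)
        df_ci = pd.DataFrame(
            {
                "study_id": ["a"],
                "parameter": ["b"],
                "estimate": [1.0],
                "ci_lower": [1.0 - z * 0.5],
                "ci_upper": [1.0 + z * 0.5],
            }
        )
        e1 = effects_from_frame(df_se)[0]
        e2 = effects_from_frame(df_ci)[0]
        assert e1.variance == pytest.approx(e2.variance, rel=1e-9)


estimate_lists = st.lists(
    st.tuples(
        st.floats(-50, 50),
        st.floats(1e-3, 10.0),
    ),
    min_size=2,
    max_size=8,
)


@settings(derandomize=True, max_examples=60)
@given(estimate_lists)
def test_pooled_estimate_is_convex_combination(pairs):
    ests = _effects(pairs)
    for res in (pool_fixed(ests), pool_random(ests)):
        lo = min(p[0] for p in pairs) - 1e-9
        hi = max(p[0] for p in pairs) + 1e-9
        assert lo <= res.pooled <= hi
        assert res.tau2 >= 0.0
        assert 0.0 <= res.I2 < 1.0


@settings(derandomize=True, max_examples=60)
@given(estimate_lists)
def test_random_ci_never_narrower_than_fixed(pairs):
    ests = _effects(pairs)
    f, r = pool_fixed(ests), pool_random(ests)
    assert (r.ci[1] - r.ci[0]) >= (f.ci[1] - f.ci[0]) - 1e-9


@settings(derandomize=True, max_examples=30)
@given(estimate_lists, st.randoms(use_true_random=False))
def test_pooling_is_permutation_invariant(pairs, rnd):
    ests = _effects(pairs)
    shuffled = list(ests)
    rnd.shuffle(shuffled)
    assert pool_fixed(shuffled).pooled == pytest.approx(
        pool_fixed(ests).pooled, rel=1e-9
    )
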