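"""ANOVA, BH, variance-prior fit, moderated t and the S0 volcano rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from endoprot.differential import (
    ModeratedVariancePrior,
    VolcanoParams,
    anova_scan,
    bh_adjust,
    fit_variance_prior,
    moderated_t,
    s0_significance,
    trigamma_inverse,
)
from endoprot.errors import ValidationError
from endoprot.io_tables import SampleAnnotation

from conftest import make_matrix


def two_group_setup(g1, g0):
    """ExpressionMatrix + annotations from per-group value rows."""
    g1, g0 = np.atleast_2d(g1), np.atleast_2d(g0)
    vals = np.hstack([g1, g0]).astype(float)
    samples = [f"CC_{i}" for i in range(g1.shape[1])] + [
        f"EMT_{i}" for i in range(g0.shape[1])
    ]
    ann = [SampleAnnotation(s, s.split("_")[0]) for s in samples]
    return make_matrix(vals, samples=samples), ann


def brute_anova(groups):
    """One-way F by explicit sum-of-squares decomposition."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(all_vals) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, stats.f.sf(F, dfb, dfw)


class TestAnova:
    def test_constant_protein_convention(self):
        m, ann = two_group_setup([[5.0, 5.0, 5.0]], [[5.0, 5.0]])
        res = anova_scan(m, ann, ["CC", "EMT"])
        assert res["F"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_toy_three_group_matches_bruteforce(self):
        groups = [[1.0, 2, 3], [2.0, 3, 4], [10.0, 11, 12]]
        vals = np.concatenate(groups)[None, :]
        samples = (
            [f"CC_{i}" for i in range(3)]
            + [f"EMT_{i}" for i in range(3)]
            + [f"END_{i}" for i in range(3)]
        )
        ann = [SampleAnnotation(s, s.split("_")[0]) for s in samples]
        res = anova_scan(make_matrix(vals, samples=samples), ann,
                         ["CC", "EMT", "END"])
        F, p = brute_anova(groups)
        assert res["F"].iloc[0] == pytest.approx(F, abs=1e-10)
        assert res["p"].iloc[0] == pytest.approx(p, abs=1e-10)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        vals1 = rng.normal(size=(40, 4))
        vals0 = rng.normal(0.5, 1.0, size=(40, 5))
        m, ann = two_group_setup(vals1, vals0)
        res = anova_scan(m, ann, ["CC", "EMT"])
        t = stats.ttest_ind(vals1, vals0, axis=1).statistic
        np.testing.assert_allclose(res["F"], t**2, atol=1e-10)

    def test_group_too_small_rejected(self):
        m, ann = two_group_setup([[1.0, 2.0]], [[3.0]])
        with pytest.raises(ValidationError, match="EMT"):
            anova_scan(m, ann, ["CC", "EMT"])


def brute_bh(p):
    """Step-up adjusted values by direct definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


class TestBhAdjust:
    def test_hand_example(self):
        q, flags = bh_adjust([0.01, 0.02, 0.03, 0.04], level=0.05)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)
        assert flags.all()

    def test_single_and_all_ones(self):
        q, _ = bh_adjust([0.3])
        assert q[0] == pytest.approx(0.3)
        q, flags = bh_adjust([1.0, 1.0, 1.0])
        assert (q == 1.0).all() and not flags.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=10))
    def test_matches_stepup_oracle(self, pvals):
        q, _ = bh_adjust(pvals)
        np.testing.assert_allclose(q, brute_bh(pvals), atol=1e-12)


class TestVariancePrior:
    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for x in [0.05, 0.5, 2.0, 50.0]:
            y = float(polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_equal_variances_give_infinite_d0(self):
        from scipy.special import digamma

        prior = fit_variance_prior(np.full(100, 0.5), df=6)
        assert np.isinf(prior.d0)
        # s0_sq is the bias-corrected back-transform of mean log variance
        assert prior.s0_sq == pytest.approx(
            0.5 * np.exp(-digamma(3) + np.log(3)), rel=1e-9
        )

    def test_minimal_input_runs(self):
        rng = np.random.default_rng(2)
        prior = fit_variance_prior(rng.chisquare(4, 10) / 4, df=4)
        assert prior.s0_sq > 0
        assert prior.d0 > 0

    def test_too_few_rejected(self):
        with pytest.raises(ValidationError):
            fit_variance_prior(np.ones(9), df=4)

    def test_parameter_recovery_moderate_size(self):
        rng = np.random.default_rng(11)
        d0, s0sq, d, m = 4.0, 0.05, 6, 5000
        sigma2 = s0sq * d0 / rng.chisquare(d0, m)
        s2 = sigma2 * rng.chisquare(d, m) / d
        prior = fit_variance_prior(s2, df=d)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0sq, rel=0.08)


class TestModeratedT:
    def test_no_shrinkage_limit_equals_pooled_t(self):
        rng = np.random.default_rng(3)
        m, ann = two_group_setup(rng.normal(size=(30, 4)),
                                 rng.normal(size=(30, 5)))
        prior = ModeratedVariancePrior(d0=0.0, s0_sq=1.0)
        res = moderated_t(m, ann, ("CC", "EMT"), prior=prior)
        expected = stats.ttest_ind(
            m.values.iloc[:, :4], m.values.iloc[:, 4:], axis=1
        )
        np.testing.assert_allclose(res["t"], expected.statistic, atol=1e-12)
        np.testing.assert_allclose(res["p"], expected.pvalue, rtol=1e-9)

    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(4)
        m, ann = two_group_setup(rng.normal(size=(20, 3)),
                                 rng.normal(size=(20, 3)))
        prior = ModeratedVariancePrior(d0=np.inf, s0_sq=0.7)
        res = moderated_t(m, ann, ("CC", "EMT"), prior=prior)
        assert (res["s2_post"] == 0.7).all()

    def test_hand_computation(self):
        m, ann = two_group_setup([[1.0, 2, 3]], [[3.0, 4, 5]])
        prior = ModeratedVariancePrior(d0=2.0, s0_sq=1.0)
        res = moderated_t(m, ann, ("CC", "EMT"), prior=prior)
        # s1^2 = s0^2 = 1, pooled = 1, s_post^2 = (2*1 + 4*1)/6 = 1
        # t = (2 - 4)/sqrt(1 * (1/3 + 1/3)) = -2.449..., df = d0 + d = 6
        expected_t = -2.0 / np.sqrt(2.0 / 3.0)
        assert res["t"].iloc[0] == pytest.approx(expected_t, abs=1e-12)
        assert res["df"].iloc[0] == 6.0
        assert res["p_one_sided"].iloc[0] == pytest.approx(
            stats.t.sf(expected_t, 6), abs=1e-12
        )

    def test_null_p_values_uniform_with_known_prior(self):
        """Under the hierarchical variance model with the true prior given,
        moderated p-values are exactly uniform (KS at m=10000)."""
        rng = np.random.default_rng(8)
        d0, s0sq, m_prot = 6.0, 1.0, 10_000
        sigma = np.sqrt(s0sq * d0 / rng.chisquare(d0, m_prot))
        g1 = rng.normal(0, sigma[:, None], size=(m_prot, 4))
        g0 = rng.normal(0, sigma[:, None], size=(m_prot, 4))
        m, ann = two_group_setup(g1, g0)
        prior = ModeratedVariancePrior(d0=d0, s0_sq=s0sq)
        res = moderated_t(m, ann, ("CC", "EMT"), prior=prior)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01


class TestS0Significance:
    @pytest.fixture
    def components(self):
        rng = np.random.default_rng(9)
        delta = rng.normal(0, 0.3, 100)
        delta[:5] += 8.0
        se = rng.uniform(0.2, 0.6, 100)
        return delta, se

    def test_s0_zero_reduces_to_plain_bh(self, components):
        delta, se = components
        table, _ = s0_significance(delta, se, df=10,
                                   params=VolcanoParams(fdr=0.05, s0=0.0))
        p_plain = 2 * stats.t.sf(np.abs(delta / se), 10)
        _, flags = bh_adjust(p_plain, level=0.05)
        np.testing.assert_array_equal(table["significant"], flags)

    def test_huge_s0_kills_everything(self, components):
        delta, se = components
        table, curve = s0_significance(delta, se, df=10,
                                       params=VolcanoParams(s0=1e6))
        assert not table["significant"].any()
        assert curve.empty

    def test_matches_bruteforce_recomputation(self, components):
        delta, se = components
        params = VolcanoParams(fdr=0.05, s0=1.0)
        table, _ = s0_significance(delta, se, df=10, params=params)
        t_s0 = delta / (se + 1.0)
        p = 2 * stats.t.sf(np.abs(t_s0), 10)
        q = brute_bh(p)
        np.testing.assert_allclose(table["q"], q, atol=1e-12)
        np.testing.assert_array_equal(table["significant"], q <= 0.05)
        assert table["significant"].sum() == 5
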