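"""Right-boundary pi0, two-group model, conservative control, marker calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endoprot.errors import ValidationError
from endoprot.markers import (
    classify_patterns,
    conservative_control_fit,
    estimate_pi0_right_boundary,
    fit_two_group,
    transition_posteriors,
)
from endoprot.preprocess import ImputationParams, impute_downshift, to_log2
from endoprot.simulate import SimulationConfig, generate_dataset

from conftest import make_matrix


class TestPi0RightBoundary:
    def test_exact_uniform_grid(self):
        m = 1000
        p = (np.arange(1, m + 1) - 0.5) / m
        pi0 = estimate_pi0_right_boundary(p)
        assert 0.95 <= pi0 <= 1.0

    def test_all_tiny_p_gives_zero(self):
        assert estimate_pi0_right_boundary(np.full(1000, 5e-4)) == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            estimate_pi0_right_boundary(np.linspace(0.01, 0.99, 49))

    def test_mixture_recovery(self):
        errs = []
        for i in range(30):
            rng = np.random.default_rng(100 + i)
            p = np.concatenate(
                [rng.uniform(size=800), rng.beta(0.1, 10, 200)]
            )
            errs.append(estimate_pi0_right_boundary(p))
        assert abs(np.mean(errs) - 0.8) <= 0.05

    def test_signal_never_inflates_estimate(self):
        """Replacing uniform p-values by near-zero ones does not raise pi0."""
        rng = np.random.default_rng(0)
        base = rng.uniform(size=1000)
        spiked = base.copy()
        spiked[:300] = rng.beta(0.05, 20, 300)
        assert (estimate_pi0_right_boundary(spiked)
                <= estimate_pi0_right_boundary(base) + 1e-12)


class TestTwoGroupFit:
    def test_pure_null_posteriors_low(self):
        rng = np.random.default_rng(1)
        p = stats.norm.sf(rng.normal(size=10_000))
        fit = fit_two_group(p, pi0=1.0)
        assert np.median(fit.posterior_elevated) <= 0.1
        assert fit.lfdr.between(0, 1).all()

    def test_marginal_density_normalized(self):
        rng = np.random.default_rng(2)
        p = stats.norm.sf(rng.normal(size=2000))
        fit = fit_two_group(p, pi0=1.0)
        integral = np.trapezoid(fit.f_hat, fit.grid)
        assert integral == pytest.approx(1.0, abs=0.02)
        assert (fit.f_hat >= 0).all()

    def test_no_null_limit(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 0.999, 500)
        fit = fit_two_group(p, pi0=0.0)
        assert (fit.lfdr == 0).all()
        assert (fit.posterior_elevated[fit.z > 0] == 1.0).all()

    def test_spiked_score_confidently_elevated(self):
        rng = np.random.default_rng(4)
        p = stats.norm.sf(rng.normal(size=999))
        p = np.append(p, stats.norm.sf(6.0))
        fit = fit_two_group(pd.Series(p), pi0=0.95)
        assert fit.posterior_elevated.iloc[-1] >= 0.99

    def test_boundary_p_values_clamped(self):
        p = np.array([0.0, 0.5, 1.0] + [0.4] * 97)
        with pytest.warns(UserWarning, match="clamped"):
            fit = fit_two_group(p, pi0=1.0)
        assert np.isfinite(fit.z).all()

    def test_lfdr_antitonic_on_right_tail(self):
        rng = np.random.default_rng(5)
        p = stats.norm.sf(rng.normal(size=5000))
        fit = fit_two_group(p, pi0=1.0)
        order = np.argsort(fit.z.to_numpy())
        z_sorted = fit.z.to_numpy()[order]
        lfdr_sorted = fit.lfdr.to_numpy()[order]
        tail = (z_sorted > 1.0) & (z_sorted < z_sorted.max() - 0.5)
        diffs = np.diff(lfdr_sorted[tail])
        # antitonic up to small KDE wiggle
        assert np.quantile(diffs, 0.95) <= 0.02

    def test_empirical_null_close_to_theoretical_on_null_data(self):
        rng = np.random.default_rng(6)
        p = stats.norm.sf(rng.normal(size=5000))
        fit = fit_two_group(p, pi0=1.0, null="empirical")
        assert fit.f0_mean == pytest.approx(0.0, abs=0.1)
        assert fit.f0_sd == pytest.approx(1.0, abs=0.1)


class TestConservativeControl:
    def make(self, rows, samples=("END_1", "END_2", "END_3")):
        from endoprot.io_tables import SampleAnnotation

        m = make_matrix(np.asarray(rows, float), samples=list(samples))
        ann = [SampleAnnotation(s, s.split("_")[0]) for s in samples]
        return m, ann

    def test_chi_square_upper_bound(self):
        vals = [[0.0, 1.0, 2.0]]  # s2 = 1, n = 3
        m, ann = self.make(vals)
        fit = conservative_control_fit(m, ann, "END", gamma=0.25)
        expected = 2.0 / stats.chi2.ppf(0.25, 2)
        assert fit["s2_conservative"].iloc[0] == pytest.approx(expected)
        assert fit["s2"].iloc[0] == pytest.approx(1.0)

    def test_inflation_never_below_sample_variance(self):
        rng = np.random.default_rng(7)
        m, ann = self.make(rng.normal(size=(50, 3)))
        fit = conservative_control_fit(m, ann, "END", gamma=0.25)
        assert (fit["s2_conservative"] >= fit["s2"]).all()

    def test_inflation_vanishes_for_large_n_gamma_half(self):
        samples = [f"END_{i}" for i in range(400)]
        rng = np.random.default_rng(8)
        m, ann = self.make(rng.normal(size=(5, 400)), samples=samples)
        fit = conservative_control_fit(m, ann, "END", gamma=0.4999)
        ratio = fit["s2_conservative"] / fit["s2"]
        assert ratio.max() < 1.01

    def test_degenerate_constant_control(self):
        m, ann = self.make([[2.0, 2.0, 2.0]])
        fit = conservative_control_fit(m, ann, "END")
        assert fit["s2_conservative"].iloc[0] == 0.0
        assert bool(fit["degenerate"].iloc[0])

    def test_small_group_rejected(self):
        m, ann = self.make([[1.0, 2.0]], samples=("END_1", "EMT_1"))
        with pytest.raises(ValidationError, match="END"):
            conservative_control_fit(m, ann, "END")


def pipeline_matrix(cfg):
    table, annotations, truth = generate_dataset(cfg)
    m = impute_downshift(to_log2(table), ImputationParams(seed=cfg.seed))
    return m, annotations, truth


class TestTransitionPosteriors:
    def test_null_data_rarely_elevated(self):
        cfg = SimulationConfig(n_proteins=800, pattern_fractions=(0, 0, 0),
                               n_housekeeping=0,
                               cohort_sizes={"CC": 6, "EMT": 3, "END": 5},
                               seed=31)
        m, ann, _ = pipeline_matrix(cfg)
        post = transition_posteriors(m, ann, ("END", "EMT", "CC"))
        assert (post.post_first >= 0.9).mean() <= 0.10
        assert (post.post_second >= 0.9).mean() <= 0.10

    def test_effects_confined_to_their_transition(self):
        # pattern B: elevation only in END->EMT
        cfg = SimulationConfig(n_proteins=800, pattern_fractions=(0, 0.05, 0),
                               n_housekeeping=0, effect_size=3.0,
                               cohort_sizes={"CC": 6, "EMT": 3, "END": 5},
                               seed=32)
        m, ann, truth = pipeline_matrix(cfg)
        post = transition_posteriors(m, ann, ("END", "EMT", "CC"))
        b_rows = truth.pattern.reindex(m.values.index) == "B"
        assert (post.post_first[b_rows] >= 0.9).mean() > 0.3
        assert (post.post_second >= 0.9).mean() <= 0.05

    def test_conservative_inflation_reduces_null_positives(self):
        cfg = SimulationConfig(n_proteins=800, pattern_fractions=(0, 0, 0),
                               n_housekeeping=0,
                               cohort_sizes={"CC": 6, "EMT": 3, "END": 5},
                               seed=33)
        m, ann, _ = pipeline_matrix(cfg)
        from endoprot.differential import moderated_t
        from endoprot.markers import conservative_control_fit

        cons = conservative_control_fit(m, ann, "END", gamma=0.25)
        with_cons = moderated_t(m, ann, ("EMT", "END"),
                                control_variance=cons["s2_conservative"])
        plain = moderated_t(m, ann, ("EMT", "END"))
        alpha = 0.05
        assert (
            (with_cons["p_one_sided"] < alpha).sum()
            <= (plain["p_one_sided"] < alpha).sum()
        )


class TestClassifyPatterns:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (0.95, 0.95, "A"),
            (0.95, 0.10, "B"),
            (0.10, 0.95, "C"),
            (0.10, 0.10, "none"),
            (0.90, 0.90, "A"),  # threshold is inclusive
        ],
    )
    def test_rule_table(self, p1, p2, expected):
        calls = classify_patterns(pd.Series([p1]), pd.Series([p2]), tau=0.9)
        assert calls["pattern"].iloc[0] == expected
        assert bool(calls["is_marker"].iloc[0]) == (expected != "none")

    def test_all_zero_posteriors_empty_marker_set(self):
        calls = classify_patterns(pd.Series([0.0] * 5), pd.Series([0.0] * 5))
        assert not calls["is_marker"].any()

    def test_invalid_tau(self):
        with pytest.raises(ValidationError):
            classify_patterns(pd.Series([0.5]), pd.Series([0.5]), tau=1.0)
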