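"""Linear WPR models on correlation curves: priors, fits, subgroups."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import decile_groups_sort_and_cut, h1_bf10_quadrature
from wprdm.data_io import CorrelationCurve
from wprdm.wpr_inference import (
    MCMCConfig,
    assign_caution_deciles,
    caution_subgroup_wpr,
    fit_wpr_h1,
    fit_wpr_h2,
    h1_prior_slope_ordinate,
    h2_prior_delta_ordinate,
)

LEVELS = tuple(i / 6 for i in range(1, 6))


def _curve(r, n=916):
    return CorrelationCurve(levels=LEVELS, r=np.asarray(r, float), n=n)


class TestPriors:
    def test_constrained_slope_ordinate_is_twelve_sevenths(self):
        """Area of {(b0,b1) in [-1,0]^2 : b0 + (5/6) b1 > -1} is 7/12, so the
        marginal prior density of the slope at 0 is 12/7."""
        assert h1_prior_slope_ordinate(LEVELS, constrained=True) == pytest.approx(
            12 / 7, rel=1e-3
        )

    def test_unconstrained_ordinate_from_admissible_area(self):
        # quadrature vs an independent Monte-Carlo area estimate
        rng = np.random.default_rng(1)
        b = rng.uniform(-1, 1, size=(400000, 2))
        rho = b[:, :1] + b[:, 1:] * np.array(LEVELS)
        area = 4 * np.mean(np.all(np.abs(rho) < 1, axis=1))
        mc = 2.0 / area
        assert h1_prior_slope_ordinate(LEVELS, constrained=False) == pytest.approx(
            mc, rel=0.01
        )

    def test_delta_ordinate_close_to_folded_normal_mode(self):
        """The admissibility truncation only mildly reweights 2*phi(0)."""
        ord0 = h2_prior_delta_ordinate(LEVELS)
        assert ord0 == pytest.approx(2 * stats.norm.pdf(0), rel=0.10)


class TestFitH1:
    def test_no_data_returns_prior_and_unit_bf(self):
        fit = fit_wpr_h1(CorrelationCurve(levels=(), r=np.array([]), n=916))
        assert abs(fit.bf_slope.bf10 - 1.0) < 0.15
        assert fit.beta0.min() > -1 and fit.beta0.max() < 0
        assert fit.beta1.min() > -1 and fit.beta1.max() < 0

    def test_truncation_respected_in_samples(self):
        fit = fit_wpr_h1(_curve([-0.5, -0.55, -0.6, -0.65, -0.7], n=100))
        rho = fit.implied_rho()
        assert np.all(np.abs(rho) < 1)

    def test_matches_quadrature_oracle(self):
        cfg = MCMCConfig(steps=2500, burn=1000, seed=3)
        r = [-0.10, -0.13, -0.16, -0.19, -0.22]
        fit = fit_wpr_h1(_curve(r, n=200), constrained=True, mcmc_config=cfg)
        oracle = h1_bf10_quadrature(r, 200, LEVELS, constrained=True)
        assert fit.bf_slope.bf10 == pytest.approx(oracle, rel=0.10)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError, match="Fisher"):
            fit_wpr_h1(_curve([-0.2, -0.3, -0.4, -0.5, -1.0]))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            fit_wpr_h1(_curve([-0.1] * 5, n=6))

    def test_modes_agree_when_posterior_interior(self):
        """With the posterior well inside [-1,0]^2 the released-constraint fit
        reproduces the constrained one."""
        r = [-0.30, -0.36, -0.42, -0.48, -0.54]
        con = fit_wpr_h1(_curve(r, n=500), constrained=True)
        unc = fit_wpr_h1(_curve(r, n=500), constrained=False)
        assert np.mean(con.beta1) == pytest.approx(np.mean(unc.beta1), abs=0.03)
        assert np.mean(con.beta0) == pytest.approx(np.mean(unc.beta0), abs=0.03)


class TestFitH2:
    def test_no_data_returns_unit_bf(self):
        empty = CorrelationCurve(levels=(), r=np.array([]), n=916)
        fit = fit_wpr_h2(empty, empty)
        assert abs(fit.bf_delta.bf10 - 1.0) < 0.2

    def test_mismatched_levels_rejected(self):
        c1 = _curve([-0.1] * 5)
        c2 = CorrelationCurve(levels=(0.25, 0.5, 0.75), r=np.array([-0.1] * 3), n=916)
        with pytest.raises(ValueError, match="levels"):
            fit_wpr_h2(c1, c2)

    def test_strong_difficulty_difference_detected(self):
        """Hard slope clearly steeper than easy: delta posterior away from 0."""
        r_e = [-0.05, -0.07, -0.09, -0.11, -0.13]  # beta1* ~ 0.12
        r_d = [-0.10, -0.17, -0.24, -0.31, -0.38]  # beta1* ~ 0.42
        fit = fit_wpr_h2(_curve(r_e), _curve(r_d))
        assert fit.bf_delta.bf10 > 1
        assert np.median(fit.delta) > 0.2
        assert np.mean(fit.beta1_star_hard) > np.mean(fit.beta1_star_easy)


class TestCautionSubgroups:
    def test_decile_cutpoints_are_empirical_quantiles(self):
        rng = np.random.default_rng(9)
        est = pd.Series(rng.gamma(4, 0.3, size=200),
                        index=[f"p{i}" for i in range(200)])
        groups = assign_caution_deciles(est)
        cuts = np.quantile(est.to_numpy(), np.arange(1, 10) / 10)
        for g in range(9):
            assert est[groups == g].max() <= cuts[g] + 1e-12

    def test_matches_sort_and_cut_oracle(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=37)
        est = pd.Series(vals, index=[f"p{i}" for i in range(37)])
        got = assign_caution_deciles(est).to_numpy()
        expected = decile_groups_sort_and_cut(vals)
        assert np.array_equal(got, expected)

    def test_homogeneous_jittered_values_split_evenly(self):
        rng = np.random.default_rng(11)
        est = pd.Series(1.5 + 1e-6 * rng.permutation(20),
                        index=[f"p{i}" for i in range(20)])
        groups = assign_caution_deciles(est)
        assert sorted(np.bincount(groups, minlength=10)) == [2] * 10

    def test_small_groups_skipped_with_warning(self, small_scenario):
        from wprdm import data_io as dio

        _, trials, wmc, truth = small_scenario
        qm_e = dio.compute_quantile_matrix(trials, "easy")
        qm_d = dio.compute_quantile_matrix(trials, "hard")
        est = truth.participants.set_index("participant_id")["alpha"]
        cfg = MCMCConfig(steps=200, burn=200, check_convergence=False, seed=0)
        fits, summary, warns = caution_subgroup_wpr(
            qm_e, qm_d, wmc, est, mcmc_config=cfg, min_group_size=10
        )
        # 60 participants in 10 deciles -> groups of 6, all below the floor
        assert len(fits) == 0
        assert len(warns) == 10
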