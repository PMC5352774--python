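"""Wiener first-passage primitives against closed forms and simulation."""

import numpy as np
import pytest
from scipy import integrate, stats

from oracles import absorption_probability_upper, mean_decision_time_symmetric
from wprdm.wiener_core import (
    DiffusionParams,
    ParameterError,
    fpt_quantiles,
    simulate_rt_choice,
    simulate_trials,
    wiener_choice_probability,
    wiener_fpt_density,
)

P_REF = DiffusionParams(drift=2.0, boundary=1.0, start_frac=0.5, ndt=0.3)


class TestDensity:
    def test_zero_before_nondecision_time(self):
        assert wiener_fpt_density(P_REF, 0.29, "upper") == 0.0
        assert wiener_fpt_density(P_REF, -5.0, "lower") == 0.0

    @pytest.mark.parametrize(
        "params",
        [
            P_REF,
            DiffusionParams(drift=-1.0, boundary=1.6, start_frac=0.3, ndt=0.2),
            DiffusionParams(drift=0.0, boundary=0.8, start_frac=0.7),
            DiffusionParams(drift=3.5, boundary=2.2, start_frac=0.5, ndt=0.1),
        ],
    )
    def test_total_mass_and_boundary_split(self, params):
        """Upper+lower densities integrate to 1; each boundary's mass equals
        the closed-form absorption probability."""
        masses = {}
        for boundary in ("upper", "lower"):
            val, _ = integrate.quad(
                lambda t: wiener_fpt_density(params, t, boundary),
                params.ndt,
                params.ndt + 60.0,
                limit=300,
            )
            masses[boundary] = val
        assert abs(masses["upper"] + masses["lower"] - 1.0) < 1e-4
        p_up = absorption_probability_upper(
            params.drift, params.boundary, params.start_frac * params.boundary
        )
        assert abs(masses["upper"] - p_up) < 1e-4

    def test_density_continuous_and_nonnegative(self):
        ts = np.linspace(0.301, 6.0, 4000)
        d = wiener_fpt_density(P_REF, ts, "upper")
        assert np.all(d >= 0)
        assert np.all(np.abs(np.diff(d)) < 0.2)  # no jumps on a fine grid

    def test_invalid_parameters_raise(self):
        with pytest.raises(ParameterError):
            DiffusionParams(drift=1, boundary=-1)
        with pytest.raises(ParameterError):
            DiffusionParams(drift=1, boundary=1, start_frac=1.2)
        with pytest.raises(ParameterError):
            DiffusionParams(drift=1, boundary=1, ndt=-0.1)


class TestChoiceProbability:
    def test_symmetry_at_zero_drift(self):
        p = DiffusionParams(drift=0.0, boundary=1.3, start_frac=0.5)
        assert wiener_choice_probability(p) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("v", [0.3, 1.0, 2.7])
    def test_reflection_identity(self, v):
        up = wiener_choice_probability(DiffusionParams(drift=v, boundary=1.2))
        down = wiener_choice_probability(DiffusionParams(drift=-v, boundary=1.2))
        assert up + down == pytest.approx(1.0, abs=1e-12)

    def test_reference_value(self):
        assert wiener_choice_probability(P_REF) == pytest.approx(0.8808, abs=2e-4)

    def test_noise_scaling_convention(self):
        """Doubling drift, boundary and the diffusion coefficient together
        leaves the choice probability unchanged."""
        a = wiener_choice_probability(DiffusionParams(drift=1.5, boundary=1.0))
        b = wiener_choice_probability(
            DiffusionParams(drift=3.0, boundary=2.0, noise_sd=2.0)
        )
        assert a == pytest.approx(b, abs=1e-12)


class TestSimulator:
    def test_zero_drift_choice_fraction(self):
        p = DiffusionParams(drift=0.0, boundary=1.0, start_frac=0.5, ndt=0.2)
        _, upper, _ = simulate_rt_choice(p, 20000, seed=11)
        se = np.sqrt(0.25 / 20000)
        assert abs(upper.mean() - 0.5) < 3 * se

    def test_matches_closed_forms(self):
        rt, upper, _ = simulate_rt_choice(P_REF, 20000, seed=12)
        p_up = absorption_probability_upper(2.0, 1.0, 0.5)
        se_p = np.sqrt(p_up * (1 - p_up) / 20000)
        assert abs(upper.mean() - p_up) < 3 * se_p
        dt = rt - P_REF.ndt
        se_t = dt.std(ddof=1) / np.sqrt(len(dt))
        assert abs(dt.mean() - mean_decision_time_symmetric(2.0, 1.0)) < 3 * se_t

    def test_reproducible_and_rt_exceeds_ndt(self):
        a = simulate_trials(P_REF, 50, seed=5)
        b = simulate_trials(P_REF, 50, seed=5)
        assert a == b
        assert all(t.rt > P_REF.ndt for t in a if not t.censored)

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            simulate_rt_choice(P_REF, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_rt_choice(P_REF, 10, seed=1, dt=-0.1)

    @pytest.mark.parametrize(
        "params",
        [
            P_REF,
            DiffusionParams(drift=1.0, boundary=1.6, start_frac=0.4, ndt=0.25),
            DiffusionParams(drift=0.5, boundary=1.0, start_frac=0.6, ndt=0.2),
        ],
    )
    def test_simulated_rts_match_density(self, params):
        """One-sample KS of pooled simulated RTs against the density's
        distribution function is not rejected at alpha = 0.001, n = 20000."""
        rt, _, _ = simulate_rt_choice(params, 20000, seed=31)
        ts = np.linspace(params.ndt, params.ndt + 40, 24000)
        dens = wiener_fpt_density(params, ts, "upper") + wiener_fpt_density(
            params, ts, "lower"
        )
        cdf_grid = integrate.cumulative_trapezoid(dens, ts, initial=0.0)
        cdf_grid /= cdf_grid[-1]
        res = stats.kstest(rt, lambda q: np.interp(q, ts, cdf_grid))
        assert res.pvalue > 0.001


class TestQuantileShift:
    def test_drift_increase_shifts_slow_quantiles_most(self):
        """Raising drift lowers every RT quantile, and the reduction grows
        with quantile level, steepest at the .9 quantile."""
        levels = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        base = DiffusionParams(drift=1.0, boundary=1.4, start_frac=0.5, ndt=0.3)
        fast = DiffusionParams(drift=2.2, boundary=1.4, start_frac=0.5, ndt=0.3)
        q_lo = fpt_quantiles(base, levels, "upper")
        q_hi = fpt_quantiles(fast, levels, "upper")
        shift = q_lo - q_hi
        assert np.all(shift > 0)
        assert np.all(np.diff(shift) >= -1e-9)
        assert shift[-1] > shift[0]
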