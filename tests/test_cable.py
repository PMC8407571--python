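"""Cable analytics against independent numerical oracles.

The closed forms (transfer resistance, steady and transient moments over
synaptic location, integrated voltage) are validated against quadrature,
Monte-Carlo sampling of the synapse location, and a finite-difference
compartmental simulation that shares no code with the analytics.
"""

import numpy as np
import pytest
from scipy.integrate import quad

from dendronorm import cable
from dendronorm.cable import CableParameters, SynapticKernel

# the standard parameter set: r = 1 μm, g_l = 5e-5 S/cm², r_a = 100 Ω·cm,
# c = 1 μF/cm² gives λ = 1000 μm, τ_l = 20 ms
STD = dict(r=1.0, r_a=100.0, g_l=5e-5, c=1.0)


@pytest.fixture
def params():
    return CableParameters(l=500.0, **STD)


@pytest.fixture
def kernel():
    return SynapticKernel(tau_f=0.002, tau_s=0.010, theta_syn=1.0, delta_syn=1.0)


class TestCableParameters:
    def test_derived_constants(self, params):
        assert params.lam == pytest.approx(1000.0)
        assert params.L == pytest.approx(0.5)
        assert params.G_inf == pytest.approx(np.pi * 1e-9)
        assert params.tau_l == pytest.approx(0.02)

    def test_derived_fields_track_physical_fields(self):
        a = CableParameters(l=500.0, **STD)
        b = CableParameters(l=1000.0, **STD)
        assert b.L == pytest.approx(2 * a.L)
        assert b.G_inf == pytest.approx(a.G_inf)  # independent of length

    @pytest.mark.parametrize("field_", ["r", "l", "r_a", "g_l", "c"])
    def test_positive_fields_required(self, field_):
        with pytest.raises(ValueError):
            CableParameters(**{**STD, "l": 500.0, field_: 0.0})

    def test_kernel_rejects_equal_time_constants(self):
        with pytest.raises(ValueError, match="degenerate"):
            SynapticKernel(tau_f=0.01, tau_s=0.01)

    def test_kernel_integrates_to_charge(self, kernel):
        integral = quad(kernel.current, 0, 1.0)[0]
        assert integral == pytest.approx(kernel.theta_syn, rel=1e-6)


class TestTransferResistance:
    def test_sealed_end_input_resistance(self, params):
        # X = 0 reduces to coth(L)/G_inf
        expected = 1.0 / (np.tanh(params.L) * params.G_inf)
        assert cable.transfer_resistance(params, 0.0) == pytest.approx(expected)

    def test_semi_infinite_limit(self):
        long = CableParameters(l=20000.0, **STD)
        r0 = cable.transfer_resistance(long, 0.0)
        assert r0 == pytest.approx(1.0 / long.G_inf, rel=1e-6)

    def test_domain_error(self, params):
        with pytest.raises(ValueError):
            cable.transfer_resistance(params, params.L * 1.01)
        with pytest.raises(ValueError):
            cable.transfer_resistance(params, -0.1)

    def test_strictly_decreasing_in_x(self, params):
        xs = np.linspace(0, params.L, 200)
        r = cable.transfer_resistance(params, xs)
        assert np.all(np.diff(r) < 0)

    def test_soma_reduces_resistance_everywhere(self, params):
        with_soma = CableParameters(l=500.0, rho=10.0, **STD)
        xs = np.linspace(0, params.L, 20)
        assert np.all(
            cable.transfer_resistance(with_soma, xs)
            < cable.transfer_resistance(params, xs)
        )

    @pytest.mark.parametrize("l", [250.0, 500.0, 1500.0])
    @pytest.mark.parametrize("frac", [0.1, 0.5, 0.9])
    def test_agrees_with_compartmental_oracle(self, l, frac):
        p = CableParameters(l=l, **STD)
        x = frac * p.L
        analytic = float(cable.transfer_resistance(p, x))
        numeric = cable.compartmental_oracle(p, x, steady_current=1.0)
        assert numeric == pytest.approx(analytic, rel=0.01)

    def test_soma_loaded_form_against_oracle(self):
        # adjudicates the dimensionally consistent reading of the soma load
        p = CableParameters(l=500.0, rho=10.0, **STD)
        x = 0.3 * p.L
        analytic = float(cable.transfer_resistance(p, x))
        numeric = cable.compartmental_oracle(p, x, steady_current=1.0, n_compartments=800)
        assert numeric == pytest.approx(analytic, rel=0.01)


class TestSteadyMoments:
    def test_mean_is_inverse_length(self, params):
        mean, _ = cable.steady_moments(params, 1.0)
        assert mean * params.L * params.G_inf == pytest.approx(1.0)

    def test_doubling_length_halves_mean(self):
        m1, _ = cable.steady_moments(CableParameters(l=400.0, **STD), 1.0)
        m2, _ = cable.steady_moments(CableParameters(l=800.0, **STD), 1.0)
        assert m1 == pytest.approx(2.0 * m2)

    @pytest.mark.parametrize("rho", [0.0, 10.0])
    def test_variance_matches_quadrature(self, rho):
        p = CableParameters(l=600.0, rho=rho, **STD)
        delta = 2.0
        mean, var = cable.steady_moments(p, delta)
        num_mean = quad(lambda x: delta * cable.transfer_resistance(p, x), 0, p.L)[0] / p.L
        num_sq = quad(lambda x: (delta * cable.transfer_resistance(p, x)) ** 2, 0, p.L)[0] / p.L
        assert mean == pytest.approx(num_mean, rel=1e-6)
        assert var == pytest.approx(num_sq - num_mean**2, rel=1e-6)

    def test_zero_perturbation(self, params):
        assert cable.steady_moments(params, 0.0) == (0.0, 0.0)


class TestImpulseResponse:
    def test_location_average(self, params):
        # averaging over X recovers e^{-T} / (2L)
        for t_norm in (0.05, 0.5, 2.0):
            avg = quad(
                lambda x: float(cable.impulse_response(params, x, t_norm)), 0, params.L
            )[0] / params.L
            assert avg == pytest.approx(np.exp(-t_norm) / (2 * params.L), rel=1e-6)

    def test_decay_at_large_delay(self, params):
        assert cable.impulse_response(params, 0.2, 50.0) < 1e-20

    def test_truncation_self_convergence(self, params):
        coarse = cable.impulse_response(params, 0.1, 0.01)
        fine = cable.impulse_response(params, 0.1, 0.01, rtol=1e-12, max_terms=100_000)
        assert coarse == pytest.approx(fine, rel=1e-8)

    def test_negative_delay_rejected(self, params):
        with pytest.raises(ValueError):
            cable.impulse_response(params, 0.1, -0.1)


class TestMeanSynapticVoltage:
    def test_inverse_length_ratio_at_every_time(self, kernel):
        p1 = CableParameters(l=300.0, **STD)
        p2 = CableParameters(l=900.0, **STD)
        ts = np.linspace(1e-4, 0.1, 7)
        v1 = cable.mean_synaptic_voltage(p1, kernel, ts)
        v2 = cable.mean_synaptic_voltage(p2, kernel, ts)
        assert np.allclose(v1, 3.0 * v2, rtol=1e-12)

    def test_zero_charge(self, params):
        k = SynapticKernel(tau_f=0.002, tau_s=0.01, theta_syn=0.0)
        assert cable.mean_synaptic_voltage(params, k, 0.01) == 0.0

    def test_matches_convolution_quadrature(self, params, kernel):
        for t in (0.005, 0.02, 0.06):
            num = quad(
                lambda u: kernel.current(u)
                * np.exp(-(t - u) / params.tau_l)
                / (2 * params.L),
                0,
                t,
            )[0]
            closed = float(cable.mean_synaptic_voltage(params, kernel, t))
            assert closed == pytest.approx(num, rel=1e-3)

    def test_coincident_time_constants_rejected(self, params):
        k = SynapticKernel(tau_f=params.tau_l, tau_s=0.01)
        with pytest.raises(ValueError, match="degenerate"):
            cable.mean_synaptic_voltage(params, k, 0.01)


def _voltage_at_location(params, kernel, x, t, n_modes=400):
    """Independent per-location transient: cosine-mode convolution sum."""
    n = np.arange(1, n_modes + 1)
    tau_n = params.tau_n(n)

    def conv(tau_mode):
        tf, ts = kernel.tau_f, kernel.tau_s
        return tf * tau_mode / (tf - tau_mode) * (
            np.exp(-t / tf) - np.exp(-t / tau_mode)
        ) - ts * tau_mode / (ts - tau_mode) * (np.exp(-t / ts) - np.exp(-t / tau_mode))

    mode_sum = 0.5 * conv(params.tau_l) + np.sum(
        np.cos(n * np.pi * x / params.L) * conv(tau_n)
    )
    return kernel.theta_syn / (params.L * (kernel.tau_f - kernel.tau_s)) * mode_sum


class TestVoltageVariance:
    def test_zero_charge(self, params):
        k = SynapticKernel(tau_f=0.002, tau_s=0.01, theta_syn=0.0)
        assert cable.voltage_variance(params, k, 0.01) == 0.0

    def test_truncation_self_convergence(self, params, kernel):
        coarse = cable.voltage_variance(params, kernel, 0.01)
        fine = cable.voltage_variance(params, kernel, 0.01, rtol=1e-12, max_terms=100_000)
        assert coarse == pytest.approx(fine, rel=1e-7)

    def test_monte_carlo_over_location(self, params, kernel):
        sampler = np.random.default_rng(7)
        xs = sampler.uniform(0, params.L, 4000)
        t = 0.015
        vals = np.array([_voltage_at_location(params, kernel, x, t) for x in xs])
        closed = float(cable.voltage_variance(params, kernel, t))
        assert closed == pytest.approx(vals.var(), rel=0.08)


class TestPeakVoltage:
    def test_matches_dense_grid_maximum(self, params, kernel):
        t_star, v_max = cable.peak_voltage(params, kernel)
        grid = np.linspace(1e-6, 0.2, 40_000)
        v = cable.mean_synaptic_voltage(params, kernel, grid)
        assert v_max == pytest.approx(v.max(), rel=1e-6)
        assert t_star == pytest.approx(grid[np.argmax(v)], abs=2 * (grid[1] - grid[0]))

    def test_peak_time_invariant_to_length(self, kernel):
        t1, _ = cable.peak_voltage(CableParameters(l=300.0, **STD), kernel)
        t2, _ = cable.peak_voltage(CableParameters(l=1200.0, **STD), kernel)
        assert t1 == pytest.approx(t2, rel=1e-10)

    def test_maximality(self, params, kernel):
        t_star, v_max = cable.peak_voltage(params, kernel)
        for t in np.linspace(1e-5, 0.15, 50):
            assert v_max >= float(cable.mean_synaptic_voltage(params, kernel, t)) - 1e-15


class TestTotalVoltage:
    def test_mean_matches_time_quadrature(self, params, kernel):
        mean, _ = cable.total_voltage(params, kernel)
        num = quad(
            lambda t: float(cable.mean_synaptic_voltage(params, kernel, t)),
            0,
            2.0,
            limit=200,
        )[0]
        assert mean == pytest.approx(num, rel=1e-6)
        assert mean == pytest.approx(
            kernel.theta_syn * params.tau_l / (2 * params.L), rel=1e-12
        )

    def test_mean_independent_of_synaptic_time_constants(self, params):
        k1 = SynapticKernel(tau_f=0.001, tau_s=0.05)
        k2 = SynapticKernel(tau_f=0.004, tau_s=0.01)
        assert cable.total_voltage(params, k1)[0] == cable.total_voltage(params, k2)[0]

    def test_zero_charge(self, params):
        k = SynapticKernel(tau_f=0.002, tau_s=0.01, theta_syn=0.0)
        assert cable.total_voltage(params, k) == (0.0, 0.0)

    def test_variance_monte_carlo(self, params, kernel):
        # V(X) = Θ/L (τ_l/2 + Σ cos(nπX/L) τ_n): sample X, integrate modes
        sampler = np.random.default_rng(11)
        n = np.arange(1, 4000)
        tau_n = params.tau_n(n)
        xs = sampler.uniform(0, params.L, 6000)
        vals = np.array(
            [
                kernel.theta_syn
                / params.L
                * (params.tau_l / 2 + np.sum(np.cos(n * np.pi * x / params.L) * tau_n))
                for x in xs
            ]
        )
        _, var = cable.total_voltage(params, kernel)
        assert var == pytest.approx(vals.var(), rel=0.08)


class TestCompartmentalOracle:
    def test_zero_input_is_silent(self, params):
        assert cable.compartmental_oracle(params, 0.2, steady_current=0.0) == 0.0

    def test_richardson_refinement(self, params):
        v1 = cable.compartmental_oracle(params, 0.3, steady_current=1.0, n_compartments=400)
        v2 = cable.compartmental_oracle(params, 0.3, steady_current=1.0, n_compartments=800)
        assert abs(v2 - v1) / abs(v2) < 1e-3

    def test_compartment_floor(self, params):
        with pytest.raises(ValueError):
            cable.compartmental_oracle(params, 0.1, steady_current=1.0, n_compartments=50)

    def test_transient_matches_mode_sum(self, params, kernel):
        x = 0.4 * params.L
        times, trace = cable.compartmental_oracle(
            params, x, kernel=kernel, n_compartments=300, t_stop=0.05
        )
        convert = cable.charge_to_voltage(params)
        i = len(times) // 2
        expected = _voltage_at_location(params, kernel, x, times[i]) * convert
        assert trace[i] == pytest.approx(expected, rel=0.01)
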