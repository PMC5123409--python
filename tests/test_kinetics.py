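"""Forward kinetic model: rates, steady states, propagation, conservation."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import photoxs as px
from photoxs.kinetics import (
    DARK,
    KineticsError,
    LightPhase,
    LightProtocol,
    LightSource,
    Structure,
    active_adapted_state,
    photo_rate,
    photo_rates,
)


def monochrome(center: float, fluence: float) -> LightSource:
    """All fluence in the single bin at ``center``."""
    grid = np.arange(400.0, 801.0)
    z = np.zeros_like(grid)
    z[np.searchsorted(grid, center)] = fluence
    return LightSource(grid, z)


def simple_model(phi_A=0.2, phi_I=0.4, beta=0.05, sigma_peak=1.0e4):
    grid = np.arange(400.0, 801.0)
    cs = px.CrossSectionSet(
        grid,
        px.synthgen.gaussian_band(grid, 660.0, 40.0, sigma_peak),
        px.synthgen.gaussian_band(grid, 550.0, 40.0, sigma_peak),
    )
    return px.PhotoreceptorModel(
        cs, px.QuantumYields(phi_A, phi_I), px.ReversionModel.single(beta)
    )


class TestPhotoRate:
    def test_single_bin_product(self):
        """sigma = 1e4 m^2/mol in one bin under 11 umol/m^2/s gives 0.11 s^-1."""
        grid = np.arange(400.0, 801.0)
        sigma = np.zeros_like(grid)
        sigma[np.searchsorted(grid, 660.0)] = 1.0e4
        assert photo_rate(grid, sigma, monochrome(660.0, 11.0)) == pytest.approx(0.11)

    def test_disjoint_support_is_zero(self):
        grid = np.arange(400.0, 801.0)
        sigma = px.synthgen.gaussian_band(grid, 450.0, 10.0, 1e4)
        sigma[grid > 500] = 0.0
        assert photo_rate(grid, sigma, monochrome(660.0, 11.0)) == 0.0

    def test_dark_is_zero(self):
        grid = np.arange(400.0, 801.0)
        assert photo_rate(grid, np.ones_like(grid), DARK) == 0.0

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_linearity_in_fluence(self, scale):
        grid = np.arange(400.0, 801.0)
        sigma = px.synthgen.gaussian_band(grid, 660.0, 40.0, 1e4)
        base = photo_rate(grid, sigma, monochrome(660.0, 11.0))
        scaled = photo_rate(grid, sigma, monochrome(660.0, 11.0 * scale))
        assert scaled == pytest.approx(scale * base, rel=1e-12)

    def test_grid_mismatch_without_interpolation_errors(self):
        grid = np.arange(400.0, 801.0)
        light = LightSource(np.arange(500.0, 701.0), np.ones(201))
        with pytest.raises(KineticsError):
            photo_rate(grid, np.ones_like(grid), light, interpolate=False)


class TestSteadyState:
    def test_pure_active_when_only_activating_channel(self):
        """Light entirely inside the sigma_I band with beta = 0 drives c_A -> 1."""
        model = simple_model(beta=0.0)
        ss = px.steady_state(model, monochrome(660.0, 11.0))
        assert ss.c_A == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_rates_give_half(self):
        model = simple_model(beta=0.0)
        grid = model.wavelengths
        z = np.zeros_like(grid)
        # equal fluence at both band peaks -> k_I = k_A by construction
        z[np.searchsorted(grid, 660.0)] = 5.0
        z[np.searchsorted(grid, 550.0)] = 5.0
        ss = px.steady_state(model, LightSource(grid, z))
        assert ss.c_A == pytest.approx(0.5, rel=1e-12)

    def test_printed_formula_value(self):
        """k_I = 0.10, k_A = 0.05, beta = 0.05 -> c_A = 0.10/0.20 = 0.5."""
        grid = np.arange(400.0, 801.0)
        sigma_I = np.zeros_like(grid)
        sigma_A = np.zeros_like(grid)
        sigma_I[np.searchsorted(grid, 660.0)] = 0.10 / (11.0 * 1e-6)
        sigma_A[np.searchsorted(grid, 660.0)] = 0.05 / (11.0 * 1e-6)
        model = px.PhotoreceptorModel(
            px.CrossSectionSet(grid, sigma_I, sigma_A),
            px.QuantumYields(0.5, 0.5),
            px.ReversionModel.single(0.05),
        )
        ss = px.steady_state(model, monochrome(660.0, 11.0))
        assert ss.c_A == pytest.approx(0.5, rel=1e-12)

    def test_all_rates_zero_errors(self):
        model = simple_model(beta=0.0)
        with pytest.raises(KineticsError):
            px.steady_state(model, DARK)


class TestPropagate:
    def test_dark_half_life(self):
        """Single pool, c_A(0) = 1, beta = 0.005: c_A(ln2/beta) = 1/2."""
        model = simple_model(beta=0.005)
        c0 = active_adapted_state(model)
        t_half = math.log(2) / 0.005
        states = px.propagate(model, LightProtocol.constant(DARK), c0, [t_half])
        assert states[0].c_A == pytest.approx(0.5, rel=1e-12)

    def test_dark_without_reversion_is_constant(self):
        model = simple_model(beta=0.0)
        c0 = active_adapted_state(model)
        states = px.propagate(model, LightProtocol.constant(DARK), c0, [0.0, 10.0, 1e6])
        assert all(s.c_A == 1.0 for s in states)

    @pytest.mark.parametrize("structure", [Structure.MONOMER, Structure.DIMER])
    def test_matches_ode_oracle(self, structure):
        """Closed-form / expm propagation equals brute-force ODE integration."""
        rng = np.random.default_rng(42)
        grid = np.arange(600.0, 761.0)
        light = px.gaussian_led(660.0, 20.0, 11.0, grid)
        n_draws = 10 if structure is Structure.MONOMER else 5
        for _ in range(n_draws):
            amp_I, amp_A = rng.uniform(1e3, 3e5, size=2)
            beta1, beta2 = sorted(rng.uniform(1e-5, 1e-2, size=2), reverse=True)
            alpha = rng.uniform(0.1, 0.9)
            cs = px.CrossSectionSet(
                grid,
                px.synthgen.gaussian_band(grid, 660.0, 50.0, amp_I),
                px.synthgen.gaussian_band(grid, 700.0, 50.0, amp_A),
            )
            model = px.PhotoreceptorModel(
                cs,
                px.QuantumYields(0.2, 0.3),
                px.ReversionModel(
                    (px.ReversionPool(alpha, beta1), px.ReversionPool(1 - alpha, beta2))
                ),
                structure=structure,
            )
            k_I, k_A = photo_rates(model, light)
            t_end = 30.0
            if structure is Structure.MONOMER:
                c0 = np.zeros(2)

                def rhs(t, a):
                    return k_I * (1 - a) - (k_A + model.reversion.betas) * a

                sol = solve_ivp(
                    rhs, (0, t_end), c0, rtol=1e-12, atol=1e-14, dense_output=True
                )
                oracle = model.reversion.alphas @ sol.y[:, -1]
            else:
                from photoxs.kinetics import _dimer_generator

                q = _dimer_generator(k_I, k_A, model.beta_AA, model.beta_AI)
                sol = solve_ivp(
                    lambda t, p: q @ p,
                    (0, t_end),
                    [1.0, 0.0, 0.0],
                    rtol=1e-12,
                    atol=1e-14,
                )
                oracle = sol.y[1, -1] + 2 * sol.y[2, -1]
            states = px.propagate(
                model,
                LightProtocol.constant(light),
                None,
                [t_end],
            )
            assert states[0].c_A == pytest.approx(oracle, abs=1e-8)

    def test_negative_duration_errors(self):
        with pytest.raises(KineticsError):
            LightPhase(-1.0, DARK)


class TestInvariants:
    @pytest.mark.parametrize("preset_name", ["redgreen", "dual_reversion", "dimer"])
    def test_conservation_along_trajectories(self, preset_name):
        """sum_k c^k = n_c at every time point of every trajectory."""
        preset = px.make_preset(preset_name)
        model = preset.model
        protocol = LightProtocol(
            (LightPhase(20.0, preset.light_act), LightPhase(math.inf, preset.light_inact))
        )
        times = np.linspace(0.0, 100.0, 23)
        for state in px.propagate(model, protocol, None, times):
            assert state.c_A + state.c_I == pytest.approx(model.n_c, abs=1e-10)
            assert -1e-12 <= state.c_A <= model.n_c + 1e-12

    def test_monotone_approach_to_steady_state(self):
        model = simple_model(beta=0.01)
        light = monochrome(660.0, 11.0)
        target = px.steady_state(model, light).c_A
        traj = px.propagate(
            model, LightProtocol.constant(light), None, np.linspace(0, 200, 50)
        )
        c = np.array([s.c_A for s in traj])
        assert np.all(np.diff(c) >= -1e-12)
        assert np.all(c <= target + 1e-12)

    @pytest.mark.parametrize("preset_name", ["overlap680", "dimer"])
    def test_saturation_forgets_initial_condition(self, preset_name):
        """t -> inf fractions are independent of the preparatory state."""
        preset = px.make_preset(preset_name)
        model = preset.model
        protocol = LightProtocol.saturating(preset.light_inact)
        from photoxs.kinetics import dark_adapted_state

        end_a = px.propagate(model, protocol, active_adapted_state(model))
        end_b = px.propagate(model, protocol, dark_adapted_state(model))
        assert end_a.c_A == pytest.approx(end_b.c_A, abs=1e-8)

    def test_dark_decay_matches_pool_weighted_exponentials(self):
        """After light-off, the normalised active decay is the analytic
        sum of per-pool exponentials with the light-off active weights."""
        preset = px.make_preset("dual_reversion")
        model = preset.model
        start = px.steady_state(model, preset.light_act)
        times = np.array([0.0, 50.0, 200.0, 1000.0, 5000.0])
        traj = px.propagate(model, LightProtocol.constant(DARK), start, times)
        c = np.array([s.c_A for s in traj])
        weights = model.reversion.alphas * start.values  # alpha_j * a_j(0)
        analytic = np.array(
            [weights @ np.exp(-model.reversion.betas * t) for t in times]
        )
        np.testing.assert_allclose(c, analytic, rtol=1e-12)


class TestValidation:
    def test_fluence_must_be_nonnegative(self):
        grid = np.arange(400.0, 405.0)
        with pytest.raises(KineticsError):
            LightSource(grid, -np.ones_like(grid))

    def test_grid_must_increase(self):
        with pytest.raises(KineticsError):
            LightSource(np.array([400.0, 399.0]), np.array([1.0, 1.0]))

    def test_pool_fractions_must_sum_to_one(self):
        with pytest.raises(KineticsError):
            px.ReversionModel((px.ReversionPool(0.5, 0.1), px.ReversionPool(0.4, 0.01)))

    def test_quantum_yields_in_unit_interval(self):
        with pytest.raises(KineticsError):
            px.QuantumYields(0.0, 0.5)
        with pytest.raises(KineticsError):
            px.QuantumYields(0.5, 1.5)
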