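"""Implicit (X1, X2) equations, extinction families and the R bound."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import photoxs as px
from photoxs.kinetics import Structure
from photoxs.searchspace import (
    SaturatedPair,
    SearchSpaceError,
    build_search_space,
    compute_R,
    effective_beta,
    epsilon_from_X,
    epsilon_hat_from_X,
    solve_X,
)


def pair_and_inputs(preset, dataset):
    pair = SaturatedPair.from_series(dataset["forward"], dataset["reverse"])
    m = preset.model
    return pair, m, (preset.light_act, preset.light_inact)


def solve_at_truth(preset, dataset, tol=1e-9):
    pair, m, lights = pair_and_inputs(preset, dataset)
    x = solve_X(
        m.yields,
        pair,
        m.reversion,
        lights,
        c_tot=m.c_tot,
        path_length=m.path_length,
        structure=m.structure,
        tol=tol,
    )
    return pair, m, lights, x


class TestSolveX:
    def test_pure_state_system_gives_unit_interval_endpoints(self, redgreen):
        """Non-overlapping bands, beta = 0: (X1, X2) = (1, 0), so eps_I is the
        inactive-saturated spectrum and eps_A the active-saturated one."""
        preset, dataset = redgreen
        pair, m, lights, x = solve_at_truth(preset, dataset)
        # bands overlap only through far Gaussian tails, so the endpoints are
        # pure to ~1e-5
        assert x[0] == pytest.approx(1.0, abs=1e-4)
        assert x[1] == pytest.approx(0.0, abs=1e-4)
        eh_I, eh_A = epsilon_hat_from_X(x, pair)
        np.testing.assert_allclose(eh_I, pair.A_sat_inact, atol=1e-4)
        np.testing.assert_allclose(eh_A, pair.A_sat_act, atol=1e-4)

    @pytest.mark.parametrize(
        "preset_name", ["overlap680", "dual_reversion", "dimer", "noisy_rf"]
    )
    def test_residuals_below_tolerance_at_truth(self, preset_name):
        preset = px.make_preset(preset_name)
        preset = dataclasses.replace(preset, noise_cv=0.0)
        dataset = px.generate_dataset(preset)
        pair, m, lights, x = solve_at_truth(preset, dataset)
        from photoxs.searchspace import _fractions_for_X

        c_act, c_inact = _fractions_for_X(
            np.array(x), m.yields, pair, m.reversion, lights, m.structure,
            m.c_tot, m.path_length,
        )
        r1 = x[0] + (x[1] - x[0]) * c_act
        r2 = x[0] + (x[1] - x[0]) * c_inact - 1.0
        assert abs(r1) < 1e-9 and abs(r2) < 1e-9

    def test_residual_oracle_on_random_systems(self):
        """The returned pair satisfies the implicit equations on random
        synthetic systems (residuals checked independently of the solver)."""
        rng = np.random.default_rng(7)
        grid = np.arange(550.0, 801.0)
        lights = (
            px.gaussian_led(660.0, 20.0, 11.0, grid),
            px.gaussian_led(720.0, 20.0, 11.0, grid),
        )
        for _ in range(10):
            cs = px.CrossSectionSet(
                grid,
                px.synthgen.gaussian_band(grid, rng.uniform(640, 680), 60.0, 2e5),
                px.synthgen.gaussian_band(grid, rng.uniform(700, 740), 60.0, 1e5),
            )
            model = px.PhotoreceptorModel(
                cs,
                px.QuantumYields(rng.uniform(0.05, 0.5), rng.uniform(0.05, 0.5)),
                px.ReversionModel.single(rng.uniform(0.0, 0.01)),
            )
            import math

            sat_act = px.simulate_absorbance(
                model, px.LightProtocol.saturating(lights[1]),
                px.LightProtocol.constant(lights[0]), [math.inf],
            ).absorbance[0]
            sat_inact = px.simulate_absorbance(
                model, px.LightProtocol.saturating(lights[0]),
                px.LightProtocol.constant(lights[1]), [math.inf],
            ).absorbance[0]
            pair = SaturatedPair(grid, sat_act, sat_inact)
            phi = px.QuantumYields(rng.uniform(0.05, 0.9), rng.uniform(0.05, 0.9))
            x = solve_X(
                phi, pair, model.reversion, lights,
                c_tot=model.c_tot, path_length=model.path_length,
            )
            from photoxs.searchspace import _fractions_for_X

            c_act, c_inact = _fractions_for_X(
                np.array(x), phi, pair, model.reversion, lights,
                Structure.MONOMER, model.c_tot, model.path_length,
            )
            assert abs(x[0] + (x[1] - x[0]) * c_act) < 1e-9
            assert abs(x[0] + (x[1] - x[0]) * c_inact - 1.0) < 1e-9

    def test_reversion_lowers_activating_photoequilibrium(self, noisy_rf):
        """Raising beta monotonically lowers the saturated active fraction."""
        preset, _ = noisy_rf
        m = preset.model
        fracs = []
        for beta in [0.0, 0.005, 0.05, 0.5]:
            model = dataclasses.replace(m, reversion=px.ReversionModel.single(beta))
            fracs.append(px.steady_state(model, preset.light_act).c_A)
        assert all(a > b for a, b in zip(fracs, fracs[1:]))


class TestEpsilonFromX:
    def test_unit_interval_endpoints(self, redgreen):
        preset, dataset = redgreen
        pair, m, _ = pair_and_inputs(preset, dataset)
        eh_I, eh_A = epsilon_hat_from_X((1.0, 0.0), pair)
        np.testing.assert_allclose(eh_I, pair.A_sat_inact, rtol=1e-10, atol=1e-14)
        np.testing.assert_array_equal(eh_A, pair.A_sat_act)
        eh_I, eh_A = epsilon_hat_from_X((0.0, 0.0), pair)
        np.testing.assert_array_equal(eh_I, pair.A_sat_act)
        np.testing.assert_array_equal(eh_A, pair.A_sat_act)

    def test_output_is_affine_combination(self, overlap680):
        """Every eps spectrum is pointwise affine in the two saturated inputs."""
        preset, dataset = overlap680
        pair, m, _ = pair_and_inputs(preset, dataset)
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = tuple(rng.uniform(-3, 3, size=2))
            eh_I, eh_A = epsilon_hat_from_X(x, pair)
            oracle_I = (1 - x[0]) * pair.A_sat_act + x[0] * pair.A_sat_inact
            oracle_A = (1 - x[1]) * pair.A_sat_act + x[1] * pair.A_sat_inact
            np.testing.assert_allclose(eh_I, oracle_I, rtol=1e-12, atol=1e-15)
            np.testing.assert_allclose(eh_A, oracle_A, rtol=1e-12, atol=1e-15)

    @pytest.mark.parametrize("preset_name", ["overlap680", "dual_reversion", "dimer"])
    def test_true_phi_reproduces_generating_epsilon(self, preset_name):
        """At the generating quantum yields the implicit solve returns the
        generating extinction spectra (self-consistency of the family)."""
        preset = px.make_preset(preset_name)
        dataset = px.generate_dataset(preset)
        pair, m, lights, x = solve_at_truth(preset, dataset)
        eps_I, eps_A = epsilon_from_X(x, pair, m.c_tot, m.path_length, m.n_c)
        np.testing.assert_allclose(
            eps_I, m.epsilon_I, atol=1e-6 * m.epsilon_I.max()
        )
        np.testing.assert_allclose(
            eps_A, m.epsilon_A, atol=1e-6 * m.epsilon_A.max()
        )


class TestComputeR:
    @pytest.mark.parametrize(
        "preset_name", ["redgreen", "overlap680", "dual_reversion", "dimer"]
    )
    def test_forward_model_oracle(self, preset_name):
        """R evaluated from the implicit solution matches Phi_A/Phi_I of the
        generating model to 1e-6 (independent forward-model derivation).

        The X -> R map amplifies the solve tolerance when the system is
        nearly pure-state (X2 ~ 1e-5 for redgreen), so the solve runs tight
        here: this checks the formula, not the default tolerance."""
        preset = px.make_preset(preset_name)
        dataset = px.generate_dataset(preset)
        pair, m, lights, x = solve_at_truth(preset, dataset, tol=1e-13)
        eps = epsilon_from_X(x, pair, m.c_tot, m.path_length, m.n_c)
        beta_eff = effective_beta(m, preset.light_act)
        r, r_o = compute_R(m.yields, x, eps, beta_eff, lights, pair.wavelengths, m.n_c)
        assert r == pytest.approx(m.yields.R, rel=1e-6)

    def test_reversion_free_R_equals_Ro(self, overlap680):
        preset, dataset = overlap680
        pair, m, lights, x = solve_at_truth(preset, dataset)
        eps = epsilon_from_X(x, pair, m.c_tot, m.path_length, m.n_c)
        r, r_o = compute_R(m.yields, x, eps, 0.0, lights, pair.wavelengths)
        assert r == r_o

    def test_reversion_strictly_lowers_R(self, dual_reversion):
        preset, dataset = dual_reversion
        pair, m, lights, x = solve_at_truth(preset, dataset)
        eps = epsilon_from_X(x, pair, m.c_tot, m.path_length, m.n_c)
        beta_eff = effective_beta(m, preset.light_act)
        r, r_o = compute_R(m.yields, x, eps, beta_eff, lights, pair.wavelengths)
        assert beta_eff > 0
        assert r < r_o

    def test_degenerate_X1_errors(self, overlap680):
        preset, dataset = overlap680
        pair, m, lights = pair_and_inputs(preset, dataset)
        eps = epsilon_from_X((1.0, 0.0), pair, m.c_tot, m.path_length)
        with pytest.raises(SearchSpaceError):
            compute_R(m.yields, (0.0, 0.5), eps, 0.0, lights, pair.wavelengths)


@pytest.fixture(scope="module")
def small_space(noisy_rf_result):
    return noisy_rf_result.space


class TestBuildSearchSpace:
    def test_bound_chain_over_grid(self, small_space):
        """R <= R^o <= R^max wherever the grid converged."""
        ok = np.isfinite(small_space.R) & np.isfinite(small_space.R_o)
        assert ok.sum() > 0.5 * small_space.R.size
        assert np.all(small_space.R[ok] <= small_space.R_o[ok] + 1e-9)
        valid = ok & (small_space.R_o > 0)
        assert np.all(small_space.R_o[valid] <= small_space.R_max + 1e-9)

    def test_R_max_bounds_true_ratio(self, noisy_rf, small_space):
        preset, _ = noisy_rf
        assert small_space.R_max >= preset.model.yields.R

    def test_epsilon_nonnegative_at_optimum(self, noisy_rf, small_space, dual_reversion):
        """Noiseless data give non-negative spectra at the generating yields;
        with 10 % noise only noise-scale negative lobes can appear."""
        preset, dataset = dual_reversion
        pair, m, lights = pair_and_inputs(preset, dataset)
        kw = dict(c_tot=m.c_tot, path_length=m.path_length, structure=m.structure)
        space = build_search_space(pair, m.reversion, lights, n_phi=10, **kw)
        eps_I, eps_A = space.epsilon_at(m.yields)
        assert eps_I.min() > -1e-9 * eps_I.max()
        assert eps_A.min() > -1e-9 * eps_A.max()

        noisy_preset, _ = noisy_rf
        eps_I, eps_A = small_space.epsilon_at(noisy_preset.model.yields)
        floor = -0.05 * max(eps_I.max(), eps_A.max())
        assert eps_I.min() > floor and eps_A.min() > floor

    def test_refinement_stability(self, dual_reversion):
        """Doubling the quantum-yield grid changes R^max by < 1 %."""
        preset, dataset = dual_reversion
        pair, m, lights = pair_and_inputs(preset, dataset)
        kw = dict(c_tot=m.c_tot, path_length=m.path_length, structure=m.structure)
        coarse = build_search_space(pair, m.reversion, lights, n_phi=10, **kw)
        fine = build_search_space(pair, m.reversion, lights, n_phi=20, **kw)
        assert fine.R_max == pytest.approx(coarse.R_max, rel=0.01)

    def test_resolution_floor(self, dual_reversion):
        preset, dataset = dual_reversion
        pair, m, lights = pair_and_inputs(preset, dataset)
        with pytest.raises(SearchSpaceError):
            build_search_space(
                pair, m.reversion, lights, n_phi=5,
                c_tot=m.c_tot, path_length=m.path_length,
            )
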