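"""Field solver: resistor-network oracles, linearity, conservation,
maximum principle, gradient reconstruction, and error handling."""

import numpy as np
import pytest

from pfalesion import (
    ConductivityModel,
    SingularSystemError,
    SolverConfig,
    assemble_linear_system,
    boundary_currents,
    electric_field_magnitude,
    solve_potential,
)
from conftest import A_MM, SIGMA, V_APPLIED, exact_potential, make_chain_grid

MM = 1e-3


def solve_chain(grid, sigma_cells, V=1.0):
    sys_ = assemble_linear_system(grid, sigma_cells, applied_voltage_V=V)
    A, b = sys_.reduced()
    import scipy.sparse.linalg as spla
    x = spla.spsolve(A.tocsr(), b)
    phi = np.zeros(grid.n_nodes)
    phi[sys_.free] = np.atleast_1d(x)
    phi[sys_.fixed] = sys_.fixed_values
    return phi.reshape(grid.node_shape)


class TestAssembly:
    def test_homogeneous_chain_interpolates_linearly(self):
        grid = make_chain_grid(n_cells=3)
        sigma = np.full(grid.cell_shape, 0.2)
        phi = solve_chain(grid, sigma, V=3.0)
        # interior node planes at 2/3 V and 1/3 V (linear ramp)
        assert np.allclose(phi[1], 2.0, atol=1e-12)
        assert np.allclose(phi[2], 1.0, atol=1e-12)

    def test_two_cell_series_matches_resistor_divider(self):
        grid = make_chain_grid(n_cells=2, length_mm=2.0)
        s1, s2 = 0.2, 0.7
        sigma = np.array([s1, s2]).reshape(2, 1, 1)
        phi = solve_chain(grid, sigma, V=1.0)
        # interface potential from the series divider: drop ratio R1:R2
        r1, r2 = 1 / s1, 1 / s2
        expected = 1.0 - r1 / (r1 + r2)
        assert np.allclose(phi[1], expected, atol=1e-12)

    def test_all_insulated_raises_singular_system(self):
        grid = make_chain_grid(n_cells=3)
        grid.electrode_nodes[:] = False
        grid.patch_nodes[:] = False
        with pytest.raises(SingularSystemError):
            assemble_linear_system(grid, np.full(grid.cell_shape, 0.2))

    def test_nonpositive_conductivity_rejected(self):
        grid = make_chain_grid(n_cells=3)
        sigma = np.full(grid.cell_shape, 0.2)
        sigma[1] = 0.0
        with pytest.raises(ValueError, match="positive"):
            assemble_linear_system(grid, sigma)


class TestFieldMagnitude:
    def test_linear_ramp_gives_uniform_field(self):
        # 100 V across 1 cm -> 100 V/cm everywhere
        grid = make_chain_grid(n_cells=5, length_mm=10.0)
        phi = np.zeros(grid.node_shape)
        phi[:] = np.linspace(100.0, 0.0, 6)[:, None, None]
        E = electric_field_magnitude(phi, grid)
        assert np.allclose(E, 100.0, rtol=1e-12)

    def test_constant_potential_gives_zero_field(self):
        grid = make_chain_grid(n_cells=5)
        E = electric_field_magnitude(np.full(grid.node_shape, 7.0), grid)
        assert np.allclose(E, 0.0)

    def test_oracle_inverse_square_field(self, oracle_grid, oracle_solution):
        cx, cy, cz = oracle_grid.cell_centers()
        r = np.sqrt(cx[:, None, None] ** 2 + cy[None, :, None] ** 2
                    + cz[None, None, :] ** 2)
        sel = (r > 2 * A_MM * MM) & (r < 6.0 * MM)
        E_exact = V_APPLIED * (A_MM * MM) / r**2 * 0.01
        rel = np.abs(oracle_solution.E_V_per_cm[sel] - E_exact[sel]) / E_exact[sel]
        assert np.median(rel) < 0.02
        assert rel.max() < 0.15


class TestSolvePotential:
    def test_zero_voltage_trivial_solution(self):
        grid = make_chain_grid(n_cells=4)
        sol = solve_potential(grid, ConductivityModel(),
                              SolverConfig(applied_voltage_V=0.0))
        assert sol.converged and sol.iterations == 1
        assert np.allclose(sol.potential, 0.0)
        assert np.allclose(sol.E_V_per_cm, 0.0)
        assert sol.electrode_current_A == pytest.approx(0.0, abs=1e-12)

    def test_oracle_potential_matches_closed_form(self, oracle_grid,
                                                  oracle_solution):
        g = oracle_grid
        rn = np.sqrt(g.x[:, None, None] ** 2 + g.y[None, :, None] ** 2
                     + g.z[None, None, :] ** 2)
        phi_exact = exact_potential(rn, A_MM * MM, V_APPLIED)
        active = oracle_solution.potential > 0
        sel = active & (rn > A_MM * MM) & (rn < 10.0 * MM / 3)
        err = np.abs(oracle_solution.potential[sel] - phi_exact[sel]) / V_APPLIED
        assert err.max() < 0.01
        # spot value: potential at r = 2a is half the applied voltage
        i = np.argmin(np.abs(g.x - 2 * A_MM * MM))
        j = np.argmin(np.abs(g.y))
        assert oracle_solution.potential[i, j, 0] == pytest.approx(
            V_APPLIED / 2, rel=0.02)

    def test_oracle_current_matches_closed_form(self, oracle_solution):
        I_exact = 2 * np.pi * SIGMA * (A_MM * MM) * V_APPLIED
        assert oracle_solution.electrode_current_A == pytest.approx(
            I_exact, rel=0.02)

    def test_maximum_principle(self, oracle_solution, slab_sweep):
        for sol in [oracle_solution] + list(slab_sweep.solutions.values()):
            assert sol.potential.min() >= -1e-9
            assert sol.potential.max() <= sol.applied_voltage_V + 1e-9

    def test_conservation(self, oracle_solution, slab_sweep):
        for sol in [oracle_solution] + list(slab_sweep.solutions.values()):
            i_el, i_pa = sol.electrode_current_A, sol.patch_current_A
            assert abs(i_el - i_pa) / i_el <= 1e-6

    def test_linearity_voltage_doubling(self, oracle_linear_pair):
        _, _, sols = oracle_linear_pair
        assert np.allclose(sols[2000.0].potential, 2 * sols[1000.0].potential,
                           atol=1e-8)
        assert np.allclose(sols[2000.0].E_V_per_cm,
                           2 * sols[1000.0].E_V_per_cm, atol=1e-10)

    def test_nonlinearity_never_decreases_current(self, coarse_slab):
        # sigma(E) >= sigma0 pointwise, so the delivered current at the same
        # voltage can only grow when the sigmoid is enabled
        grid, model = coarse_slab
        import dataclasses
        linear = dataclasses.replace(model, sigma_factor=1.0)
        cfg = SolverConfig(applied_voltage_V=1000.0)
        i_lin = solve_potential(grid, linear, cfg).electrode_current_A
        i_nl = solve_potential(grid, model, cfg).electrode_current_A
        assert i_nl >= i_lin - 1e-9

    def test_nonconvergence_is_flagged_not_silent(self):
        grid = make_chain_grid(n_cells=4)
        cfg = SolverConfig(applied_voltage_V=1000.0, picard_max_iter=1,
                           picard_tolerance=1e-12, adaptive_relaxation=False)
        sol = solve_potential(grid, ConductivityModel(), cfg)
        assert not sol.converged
        assert sol.warnings
        with pytest.warns(RuntimeWarning):
            boundary_currents(sol, grid, sol.sigma_cells)

    def test_picard_residuals_eventually_decrease(self, slab_sweep):
        # secant-accelerated iterations may wobble by one step near the
        # fixed point; the pairwise-smoothed residual sequence must fall
        for sol in slab_sweep.solutions.values():
            hist = sol.residual_history
            assert sol.converged
            smoothed = [min(a, b) for a, b in zip(hist, hist[1:])]
            assert all(b <= a * 1.05 for a, b in zip(smoothed, smoothed[1:]))
            assert hist[-1] <= min(hist[:-1])


def test_solver_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(applied_voltage_V=-1.0)
    with pytest.raises(ValueError):
        SolverConfig(relaxation=0.0)
    with pytest.raises(ValueError):
        SolverConfig(picard_tolerance=0.0)
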