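"""Shared fixtures.

The expensive objects — the production slab sweep (two nonlinear solves) and
the analytic-oracle solutions — are session-scoped and shared across test
modules; everything is deterministic, so sharing cannot couple tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from pfalesion import (
    ConductivityModel,
    ElectrodeSpec,
    LabeledGrid,
    SolverConfig,
    ThresholdSweepSpec,
    TissueGeometrySpec,
    build_hemisphere_oracle_geometry,
    build_slab_geometry,
    run_threshold_sweep,
    solve_potential,
)

# closed forms for the hemispherical electrode on a half-space with the
# analytic far-field closure: phi = V a / r, E = V a / r^2, I = 2 pi sigma a V
A_MM = 1.335  # electrode radius (8F tip radius equivalent used throughout)
V_APPLIED = 1000.0
SIGMA = 0.20


def exact_potential(r_m: np.ndarray, a_m: float, V: float) -> np.ndarray:
    return np.clip(V * a_m / np.maximum(r_m, a_m), 0.0, V)


def exact_field_V_per_cm(r_m: np.ndarray, a_m: float, V: float) -> np.ndarray:
    return V * a_m / np.maximum(r_m, a_m) ** 2 * 0.01


def lethal_radius_mm(V: float, a_mm: float, T_V_per_cm: float) -> float:
    # E(r) = V a / r^2 = T  =>  r_T = sqrt(V a / T); lengths in mm, T in V/cm
    return float(np.sqrt(V * (a_mm * 0.1) / T_V_per_cm) * 10.0)


@pytest.fixture(scope="session")
def oracle_grid() -> LabeledGrid:
    """Oracle geometry fine enough to resolve the T = 500 V/cm lesion."""
    return build_hemisphere_oracle_geometry(
        electrode_radius_mm=A_MM, domain_radius_mm=10.0, resolution_mm=0.3,
        fine_radius_mm=6.0,
    )


@pytest.fixture(scope="session")
def oracle_solution(oracle_grid):
    model = ConductivityModel(sigma_factor=1.0)
    sol = solve_potential(oracle_grid, model,
                          SolverConfig(applied_voltage_V=V_APPLIED))
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def oracle_linear_pair():
    """Constant-sigma oracle solved at 1000 V and 2000 V on one grid."""
    grid = build_hemisphere_oracle_geometry(
        electrode_radius_mm=A_MM, domain_radius_mm=8.0, resolution_mm=0.3,
        fine_radius_mm=6.0,
    )
    model = ConductivityModel(sigma_factor=1.0)
    sols = {
        V: solve_potential(grid, model, SolverConfig(applied_voltage_V=V))
        for V in (1000.0, 2000.0)
    }
    return grid, model, sols


@pytest.fixture(scope="session")
def coarse_slab():
    """Small, coarse slab for cheap nonlinear-solve tests (seconds)."""
    tissue = TissueGeometrySpec(torso_extent_mm=(50.0, 50.0, 40.0),
                                patch_size_mm=(30.0, 20.0),
                                blood_pool_depth_mm=10.0)
    grid = build_slab_geometry(tissue, ElectrodeSpec(),
                               fine_resolution_mm=0.65,
                               lateral_resolution_mm=0.65,
                               fine_halfwidth_x_mm=4.0,
                               fine_halfwidth_y_mm=3.0)
    return grid, ConductivityModel()


@pytest.fixture(scope="session")
def slab_setup():
    """The study configuration: LV-like 10 mm wall, default electrode,
    0.35 mm through-wall / 0.5 mm lateral resolution."""
    from pfalesion.reporting import GeometryConfig, build_grid
    grid = build_grid(GeometryConfig())
    model = ConductivityModel()
    return grid, model


@pytest.fixture(scope="session")
def slab_sweep(slab_setup):
    """Full production sweep: nonlinear solves at 1000 V and 2000 V,
    thresholds 200-1000 V/cm in steps of 10."""
    grid, model = slab_setup
    return run_threshold_sweep(grid, model, ThresholdSweepSpec(),
                               SolverConfig())


def make_chain_grid(sigmas_mm=None, n_cells: int = 3, length_mm: float = 3.0):
    """1-D chain of cells along x (one cell in y and z) with Dirichlet ends.

    Returns a LabeledGrid whose electrode nodes are the x = 0 end face and
    patch nodes the far end face; used for resistor-network oracles.
    """
    n = n_cells
    x = np.linspace(0.0, length_mm, n + 1) * 1e-3
    y = np.array([0.0, 1.0]) * 1e-3
    z = np.array([0.0, 1.0]) * 1e-3
    labels = np.zeros((n, 1, 1), dtype=np.int8)  # MYOCARDIUM
    el = np.zeros((n + 1, 2, 2), dtype=bool)
    pa = np.zeros((n + 1, 2, 2), dtype=bool)
    el[0] = True
    pa[-1] = True
    return LabeledGrid(x=x, y=y, z=z, labels=labels,
                       electrode_nodes=el, patch_nodes=pa,
                       meta={"kind": "chain"})
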