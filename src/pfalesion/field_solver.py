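"""Nonlinear quasi-static potential solver.

Solves div( sigma(x, |grad phi|) grad phi ) = 0 on a labeled tensor-product
grid with Dirichlet conditions on the electrode (applied peak voltage) and
the dispersive patch (ground), and natural zero-flux conditions on every
other exterior face. The field-dependent conductivity coupling is resolved
by Picard (successive-substitution) iteration with under-relaxation, which
is robust for monotone sigmoid conductivities.

Discretization: vertex-centred finite volumes. Unknowns are node potentials;
each cell contributes edge conductances sigma * (transverse area / 4) /
(edge length) to its 12 edges. The scheme is symmetric positive definite on
the free nodes, has only nonpositive off-diagonal entries (an M-matrix), and
therefore satisfies a discrete maximum principle; across material interfaces
the node-to-node conductances compose in series, i.e. the effective flux
between cell centres uses the harmonic mean of the adjacent conductivities.

Units: SI internally (metres, volts, S/m). Electric-field magnitudes cross
the module boundary in V/cm, the reporting convention of the application
(1 V/mm = 10 V/cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .conductivity import ConductivityModel, conductivity_field
from .geometry import Label, LabeledGrid

V_PER_M_TO_V_PER_CM = 0.01


class SingularSystemError(RuntimeError):
    """The assembled system has no Dirichlet constraints (pure Neumann)."""


class LinearSolveError(RuntimeError):
    """The inner linear solve failed; message names the Picard iteration."""


@dataclass(frozen=True)
class SolverConfig:
    """Iteration controls for the nonlinear solve.

    applied_voltage_V is the peak pulse voltage imposed on the electrode
    (quasi-static abstraction of the biphasic waveform). picard_tolerance
    bounds the maximum relative cell-conductivity change at the fixed point.
    """

    applied_voltage_V: float = 1000.0
    picard_tolerance: float = 1e-4
    picard_max_iter: int = 50
    relaxation: float = 0.7
    linear_solver_tolerance: float = 1e-8
    #: adapt the relaxation factor by Aitken's secant rule between
    #: iterations (greatly accelerates the slow monotone coupling mode);
    #: ``relaxation`` is the first-step / fallback factor either way
    adaptive_relaxation: bool = True

    def __post_init__(self) -> None:
        if self.applied_voltage_V < 0:
            raise ValueError("applied_voltage_V must be nonnegative")
        if not 0 < self.relaxation <= 1:
            raise ValueError("relaxation must be in (0, 1]")
        if self.picard_tolerance <= 0 or self.linear_solver_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.picard_max_iter < 1:
            raise ValueError("picard_max_iter must be >= 1")


@dataclass
class FieldSolution:
    """Converged (or flagged) solution of the potential problem."""

    potential: np.ndarray  # (nx, ny, nz) volts
    E_V_per_cm: np.ndarray  # cell_shape, field magnitude
    sigma_cells: np.ndarray  # cell_shape, S/m (0 on excluded cells)
    applied_voltage_V: float
    converged: bool
    iterations: int
    final_residual: float
    electrode_current_A: float
    patch_current_A: float
    residual_history: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


@dataclass
class LinearSystem:
    """Assembled discrete operator with Dirichlet data.

    ``K`` is the full symmetric conductance matrix over all nodes (row sums
    zero); the reduced SPD system on free nodes is K[free, free] phi_free =
    -K[free, fixed] u_fixed. ``active`` marks nodes touching at least one
    conductive cell.
    """

    K: sp.csr_matrix
    free: np.ndarray  # int indices
    fixed: np.ndarray  # int indices
    fixed_values: np.ndarray
    active: np.ndarray  # bool per node (flat)
    n_nodes: int

    def reduced(self) -> tuple[sp.csc_matrix, np.ndarray]:
        A = self.K[self.free][:, self.free].tocsc()
        b = -self.K[self.free][:, self.fixed] @ self.fixed_values
        return A, b


def _edge_conductances(grid: LabeledGrid, sigma: np.ndarray):
    """Edge conductance arrays (S) along x, y, z from per-cell sigma.

    Each cell contributes sigma * (transverse area / 4) / (edge length) to
    each of its four edges in every direction; quadrant contributions are
    kept separate long enough to apply the embedded-sphere cut-edge scales
    (when the geometry defines exact spherical Dirichlet surfaces).
    """
    spacings = (grid.dx, grid.dy, grid.dz)
    correct = bool(grid.meta.get("embedded_spheres"))
    out = []
    for axis in range(3):
        ta, tb = (i for i in range(3) if i != axis)
        sh = [1, 1, 1]
        sh[ta] = spacings[ta].size
        area_a = spacings[ta].reshape(sh)
        sh = [1, 1, 1]
        sh[tb] = spacings[tb].size
        area_b = spacings[tb].reshape(sh)
        W = sigma * area_a * area_b  # per-cell sigma * transverse area
        edge_shape = [s + 1 for s in grid.cell_shape]
        edge_shape[axis] -= 1
        edge_shape = tuple(edge_shape)
        G = np.zeros(edge_shape)
        for d1 in (0, 1):
            for d2 in (0, 1):
                sl = [slice(None)] * 3
                sl[ta] = slice(None, -1) if d1 == 1 else slice(1, None)
                sl[tb] = slice(None, -1) if d2 == 1 else slice(1, None)
                G[tuple(sl)] += W
        if correct:
            G *= _sphere_cut_scale(grid, axis, edge_shape)
        sh = [1, 1, 1]
        sh[axis] = spacings[axis].size
        G /= 4.0 * spacings[axis].reshape(sh)
        out.append(G)
    return tuple(out)


def _sphere_cut_scale(grid, axis, shape):
    """Per-edge conductance scale for the embedded-sphere (cut-edge)
    correction along one edge direction.

    Staircase Dirichlet node sets bias the represented surface radius by
    O(h). For each grid edge with exactly one endpoint in a spherical
    Dirichlet set, the conductance is rescaled to the exact distance from
    the free node to the sphere crossing along the edge line — a
    Shortley-Weller cut that restores the analytic boundary location.
    Scales are >= 1, so the M-matrix structure is kept.
    """
    spheres = grid.meta.get("embedded_spheres")
    scale = np.ones(shape)
    if not spheres:
        return scale
    min_cut = 0.05  # floor on the cut fraction to bound conditioning
    coords = (grid.x, grid.y, grid.z)
    ta, tb = (i for i in range(3) if i != axis)
    cta = coords[ta]
    ctb = coords[tb]
    ax_c = coords[axis]
    for sph in spheres:
        dmask = (grid.electrode_nodes if sph["nodes"] == "electrode"
                 else grid.patch_nodes)
        rad = sph["radius_m"]
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        d1, d2 = dmask[tuple(lo)], dmask[tuple(hi)]
        cut_edges = d1 ^ d2
        idx = np.nonzero(cut_edges)
        if idx[0].size == 0:
            continue
        x_lo = ax_c[:-1][idx[axis]]
        x_hi = ax_c[1:][idx[axis]]
        free_is_hi = d1[idx]  # Dirichlet endpoint is the low node
        x_free = np.where(free_is_hi, x_hi, x_lo)
        x_dir = np.where(free_is_hi, x_lo, x_hi)
        rho2_e = rad**2 - (cta[idx[ta]] ** 2 + ctb[idx[tb]] ** 2)
        valid = rho2_e > 0
        # the crossing root carries the sign of whichever endpoint lies
        # outside the sphere (free node for the electrode, Dirichlet node
        # for an enclosing ground shell)
        x_out = x_free if sph["inside"] else x_dir
        x_c = np.where(valid,
                       np.sign(x_out) * np.sqrt(np.maximum(rho2_e, 0.0)),
                       x_dir)
        # fraction along the edge (Dirichlet -> free) where the surface
        # sits at this quadrant's transverse offset:
        #   t >= 1: quadrant column entirely inside the conductor -> the
        #           free node touches the surface (strongest connection);
        #   t <= 0: conductor does not reach the Dirichlet node on this
        #           column -> leave the edge uncorrected;
        #   else  : standard cut to the crossing point.
        t = (x_c - x_dir) / (x_free - x_dir)
        cutfrac = np.where(valid & (t > 0.0),
                           np.clip(1.0 - t, min_cut, 1.0), 1.0)
        scale[idx] = scale[idx] / cutfrac
    return scale


def assemble_linear_system(
    grid: LabeledGrid, sigma_cells: np.ndarray, applied_voltage_V: float = 1.0
) -> LinearSystem:
    """Assemble the conductance matrix and Dirichlet data.

    ``sigma_cells`` must be strictly positive on conductive-label cells and
    zero on excluded (ELECTRODE / OUTSIDE) cells. Raises
    :class:`SingularSystemError` when no Dirichlet nodes exist (all exterior
    faces insulated) and ``ValueError`` on nonpositive conductivities.
    """
    sigma = np.asarray(sigma_cells, dtype=float)
    if sigma.shape != grid.cell_shape:
        raise ValueError("sigma_cells shape does not match grid cells")
    cond = grid.conductive_mask()
    if np.any(sigma[cond] <= 0):
        raise ValueError("conductivities must be strictly positive on all "
                         "conductive cells")
    sigma = np.where(cond, sigma, 0.0)

    nx, ny, nz = grid.node_shape
    n = nx * ny * nz
    ids = np.arange(n).reshape(nx, ny, nz)
    Gx, Gy, Gz = _edge_conductances(grid, sigma)

    rows, cols, data = [], [], []
    for G, n1, n2 in (
        (Gx, ids[:-1, :, :], ids[1:, :, :]),
        (Gy, ids[:, :-1, :], ids[:, 1:, :]),
        (Gz, ids[:, :, :-1], ids[:, :, 1:]),
    ):
        m = G > 0
        g = G[m]
        a, b = n1[m], n2[m]
        rows += [a, b, a, b]
        cols += [a, b, b, a]
        data += [g, g, -g, -g]
    K = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    active = np.asarray(K.diagonal() > 0)
    el = grid.electrode_nodes.reshape(-1) & active
    pa = grid.patch_nodes.reshape(-1) & active
    if not el.any() or not pa.any():
        raise SingularSystemError(
            "no Dirichlet (electrode/patch) faces touch the conductive "
            "region; the system is singular"
        )
    fixed_mask = el | pa
    free = np.nonzero(active & ~fixed_mask)[0]
    fixed = np.nonzero(fixed_mask)[0]
    if grid.patch_potential_per_volt is not None:
        prof = grid.patch_potential_per_volt.reshape(-1)[fixed]
        fixed_values = np.where(el[fixed], float(applied_voltage_V),
                                float(applied_voltage_V) * prof)
    else:
        fixed_values = np.where(el[fixed], float(applied_voltage_V), 0.0)
    return LinearSystem(K=K, free=free, fixed=fixed, fixed_values=fixed_values,
                        active=active, n_nodes=n)


def electric_field_magnitude(potential: np.ndarray, grid: LabeledGrid) -> np.ndarray:
    """Cellwise field magnitude |grad phi| in V/cm.

    The cell gradient component along each axis is the average of the four
    node-potential differences along that axis's cell edges; exact for
    potentials linear in each coordinate.
    """
    phi = np.asarray(potential, dtype=float)
    if phi.shape != grid.node_shape:
        raise ValueError("potential shape does not match grid nodes")

    def comp(axis, spacing):
        d = np.diff(phi, axis=axis)
        sh = [slice(None)] * 3
        shp = [1, 1, 1]
        shp[axis] = spacing.size
        d = d / spacing.reshape(shp)
        for ax in range(3):
            if ax == axis:
                continue
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(None, -1)
            hi[ax] = slice(1, None)
            d = 0.5 * (d[tuple(lo)] + d[tuple(hi)])
        return d

    gx = comp(0, grid.dx)
    gy = comp(1, grid.dy)
    gz = comp(2, grid.dz)
    return np.sqrt(gx**2 + gy**2 + gz**2) * V_PER_M_TO_V_PER_CM


def boundary_currents(
    potential, grid: LabeledGrid, sigma_cells: np.ndarray
) -> tuple[float, float]:
    """Total current (A) through the electrode and through the patch.

    Computed as the discrete flux residual of the full conductance matrix at
    each Dirichlet node set, which is exactly conservative: the two values
    agree to the linear-solver tolerance. Both are reported positive
    (source / sink orientation). Accepts a raw node-potential array or a
    :class:`FieldSolution`; a non-converged solution triggers a warning but
    still yields the currents of the field as given.
    """
    if isinstance(potential, FieldSolution):
        if not potential.converged:
            import warnings

            warnings.warn(
                "boundary currents computed from a non-converged solution",
                RuntimeWarning, stacklevel=2,
            )
        potential = potential.potential
    sys_ = assemble_linear_system(grid, sigma_cells)
    r = sys_.K @ potential.reshape(-1)
    el = grid.electrode_nodes.reshape(-1) & sys_.active
    pa = grid.patch_nodes.reshape(-1) & sys_.active
    i_el = float(r[el].sum())
    i_pa = float(-r[pa].sum())
    return i_el, i_pa


def _linear_solve(A, b, x0, rtol, lu=None, iteration=0):
    """Solve A x = b; direct when no preconditioner exists yet, else
    LU-preconditioned CG (the LU of the first Picard matrix)."""
    if b.size == 0:
        return np.zeros(0), lu
    if lu is None:
        try:
            lu = spla.splu(A, permc_spec="MMD_AT_PLUS_A")
        except RuntimeError as exc:  # pragma: no cover - singular matrix
            raise LinearSolveError(
                f"direct factorization failed at Picard iteration {iteration}: {exc}"
            )
        return lu.solve(b), lu
    M = spla.LinearOperator(A.shape, lu.solve)
    x, info = spla.cg(A, b, x0=x0, rtol=rtol, atol=0.0, M=M, maxiter=400)
    if info != 0:
        # preconditioner too stale; refactor
        try:
            lu = spla.splu(A, permc_spec="MMD_AT_PLUS_A")
        except RuntimeError as exc:  # pragma: no cover
            raise LinearSolveError(
                f"linear solve failed at Picard iteration {iteration}: {exc}"
            )
        x = lu.solve(b)
    return x, lu


def solve_potential(
    grid: LabeledGrid, model: ConductivityModel, config: SolverConfig,
    sigma_init: np.ndarray | None = None,
    phi_init: np.ndarray | None = None,
) -> FieldSolution:
    """Picard iteration for the nonlinear potential problem.

    Each iteration assembles the operator with the current conductivity
    field, solves it, recomputes the field magnitude, and proposes
    sigma(E); the residual is the maximum relative difference between the
    proposed and current conductivities over conductive cells. The
    conductivity update is under-relaxed by ``config.relaxation``.
    Non-convergence within picard_max_iter is flagged, never silent.

    ``sigma_init`` / ``phi_init`` warm-start the iteration (e.g. from a
    converged solve at a nearby voltage); they change the iteration path,
    not the fixed point.
    """
    V = config.applied_voltage_V
    cond = grid.conductive_mask()
    zeroE = np.zeros(grid.cell_shape)
    if sigma_init is not None:
        sigma = np.where(cond, np.asarray(sigma_init, dtype=float), 0.0)
        if np.any(sigma[cond] <= 0):
            raise ValueError("sigma_init must be positive on conductive cells")
    else:
        sigma = conductivity_field(model, grid, zeroE)

    phi_full = (np.zeros(grid.n_nodes) if phi_init is None
                else np.asarray(phi_init, dtype=float).reshape(-1).copy())
    sigma_lo = conductivity_field(model, grid, zeroE)
    sigma_hi = conductivity_field(model, grid,
                                  np.full(grid.cell_shape,
                                          10.0 * model.E_high_V_per_cm))
    omega = config.relaxation
    r_prev: np.ndarray | None = None
    lu = None
    history: list[float] = []
    converged = False
    iterations = 0
    resid = np.inf
    nonlinear = model.sigma_factor > 1.0 and bool(
        (grid.labels == Label.MYOCARDIUM).any()
    )

    for it in range(1, config.picard_max_iter + 1):
        iterations = it
        sys_ = assemble_linear_system(grid, sigma, V)
        A, b = sys_.reduced()
        x0 = phi_full[sys_.free]
        x, lu = _linear_solve(A, b, x0, config.linear_solver_tolerance, lu, it)
        phi_full = np.zeros(grid.n_nodes)
        phi_full[sys_.free] = x
        phi_full[sys_.fixed] = sys_.fixed_values

        phi = phi_full.reshape(grid.node_shape)
        E = electric_field_magnitude(phi, grid)
        sigma_prop = conductivity_field(model, grid, E)
        r = np.where(cond, sigma_prop - sigma, 0.0)
        delta = np.abs(r[cond]) / sigma[cond]
        resid = float(delta.max()) if delta.size else 0.0
        history.append(resid)
        if resid <= config.picard_tolerance:
            converged = True
            break
        if not nonlinear or V == 0.0:
            # linear problem: one solve is exact
            converged = True
            resid = 0.0
            history[-1] = 0.0
            break
        if config.adaptive_relaxation and r_prev is not None:
            dr = r - r_prev
            denom = float((dr * dr).sum())
            if denom > 0:
                omega = -omega * float((r_prev * dr).sum()) / denom
                omega = float(np.clip(omega, 0.1, 10.0))
        sigma = sigma + omega * r
        # the fixed point lies within the sigmoid's range, so clamping the
        # accelerated update to it is safe and keeps the operator SPD
        sigma = np.clip(sigma, sigma_lo, sigma_hi)
        sigma = np.where(cond, sigma, 0.0)
        r_prev = r

    phi = phi_full.reshape(grid.node_shape)
    E = electric_field_magnitude(phi, grid)
    i_el, i_pa = boundary_currents(phi, grid, sigma)
    warnings = []
    if not converged:
        warnings.append(
            f"Picard iteration did not converge in {iterations} iterations "
            f"(final residual {resid:.3e} > tol {config.picard_tolerance:.1e})"
        )
    return FieldSolution(
        potential=phi,
        E_V_per_cm=E,
        sigma_cells=sigma,
        applied_voltage_V=V,
        converged=converged,
        iterations=iterations,
        final_residual=resid,
        electrode_current_A=i_el,
        patch_current_A=i_pa,
        residual_history=history,
        warnings=warnings,
    )
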