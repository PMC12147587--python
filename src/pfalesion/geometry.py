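"""Labeled voxel geometries for epicardial pulsed-field ablation simulations.

Builds tensor-product graded grids emulating the open-chest setup: a focal
cylindrical tip electrode in flush perpendicular contact with the epicardium
of a myocardial slab, a blood pool beneath the wall, a surrounding
torso-conductivity block, and a grounded dispersive patch on the far face.
Also builds the hemispherical-electrode half-space geometry that admits the
closed-form potential used for solver verification.

Coordinate convention: the epicardial plane is z = 0; depth increases with
+z into the wall; the catheter axis is the z axis. Configuration lengths are
in mm; grid node coordinates are stored in metres (SI internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

MM = 1e-3  # mm -> m


class Label(IntEnum):
    """Per-cell tissue/region labels."""

    MYOCARDIUM = 0
    BLOOD = 1
    TORSO = 2
    ELECTRODE = 3
    PATCH = 4
    OUTSIDE = 5


#: labels whose cells carry current (assembled into the linear system)
CONDUCTIVE_LABELS = (Label.MYOCARDIUM, Label.BLOOD, Label.TORSO, Label.PATCH)


class GeometryConfigError(ValueError):
    """Raised when a geometry specification is inconsistent."""


@dataclass(frozen=True)
class ElectrodeSpec:
    """Focal ablation electrode: 8F (2.667 mm) cylindrical tip, 3.5 mm long.

    The French catheter scale gives 1 Fr = 1/3 mm, hence the 8F default
    diameter of 8/3 mm. Orientation is perpendicular to the epicardium with
    flush (non-indenting) contact.
    """

    diameter_mm: float = 8.0 / 3.0
    tip_length_mm: float = 3.5
    orientation: str = "perpendicular"

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.tip_length_mm <= 0:
            raise GeometryConfigError("electrode dimensions must be positive")
        if self.orientation != "perpendicular":
            raise GeometryConfigError(
                f"unsupported electrode orientation: {self.orientation!r}"
            )

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm


@dataclass(frozen=True)
class TissueGeometrySpec:
    """Slab-geometry specification (all lengths in mm).

    wall_thickness_mm: myocardial wall between z = 0 (epicardium) and
        z = wall (endocardium). ~10 mm emulates a left-ventricular,
        nontransmural regime; 3-3.7 mm a right-ventricular, transmural one.
    blood_pool_depth_mm: blood layer beneath the endocardium.
    torso_extent_mm: (x, y, z) dimensions of the torso-conductivity box.
    patch_size_mm: (x, y) footprint of the grounded dispersive patch on the
        far (z = z_max) face; default 150 x 90 mm.
    """

    wall_thickness_mm: float = 10.0
    blood_pool_depth_mm: float = 30.0
    torso_extent_mm: tuple[float, float, float] = (160.0, 120.0, 80.0)
    patch_size_mm: tuple[float, float] = (150.0, 90.0)

    def __post_init__(self) -> None:
        if self.wall_thickness_mm <= 0:
            raise GeometryConfigError("wall_thickness_mm must be positive")
        if self.blood_pool_depth_mm < 0:
            raise GeometryConfigError("blood_pool_depth_mm must be nonnegative")
        if any(e <= 0 for e in self.torso_extent_mm):
            raise GeometryConfigError("torso extents must be positive")
        px, py = self.patch_size_mm
        tx, ty, tz = self.torso_extent_mm
        if px <= 0 or py <= 0:
            raise GeometryConfigError("patch dimensions must be positive")
        if px > tx or py > ty:
            raise GeometryConfigError(
                f"patch {px} x {py} mm does not fit on the {tx} x {ty} mm "
                "torso boundary face"
            )
        depth = self.wall_thickness_mm + self.blood_pool_depth_mm
        if depth >= tz:
            raise GeometryConfigError(
                "wall + blood pool depth must be smaller than the torso z extent"
            )


@dataclass
class LabeledGrid:
    """Discretized computational domain on a tensor-product node grid.

    Nodes live at the tensor product of ``x``, ``y``, ``z`` (metres); cell
    (i, j, k) spans [x[i], x[i+1]] x [y[j], y[j+1]] x [z[k], z[k+1]] and
    carries exactly one :class:`Label`. Dirichlet boundary conditions are
    recorded as node masks (electrode at the applied voltage, patch at
    ground); every other exterior face is insulated by construction of the
    finite-volume stencil (natural zero-flux).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    labels: np.ndarray  # (ncx, ncy, ncz) int8
    electrode_nodes: np.ndarray  # (nx, ny, nz) bool, Dirichlet at +V
    patch_nodes: np.ndarray  # (nx, ny, nz) bool, Dirichlet at 0 (or profile)
    #: optional per-node Dirichlet profile on patch nodes, in volts per volt
    #: of applied voltage (used by the oracle's analytic far-field closure);
    #: None means the patch is grounded at 0 V
    patch_potential_per_volt: np.ndarray | None = None
    wall_thickness_mm: float | None = None
    fine_resolution_mm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        expected = (self.x.size - 1, self.y.size - 1, self.z.size - 1)
        if self.labels.shape != expected:
            raise GeometryConfigError(
                f"labels shape {self.labels.shape} != cell shape {expected}"
            )
        nshape = self.node_shape
        if self.electrode_nodes.shape != nshape or self.patch_nodes.shape != nshape:
            raise GeometryConfigError("Dirichlet node masks must match node shape")
        if self.electrode_nodes.any() and self.patch_nodes.any():
            if (self.electrode_nodes & self.patch_nodes).any():
                raise GeometryConfigError("a node cannot be both electrode and patch")

    # -- derived geometry -------------------------------------------------
    @property
    def node_shape(self) -> tuple[int, int, int]:
        return (self.x.size, self.y.size, self.z.size)

    @property
    def cell_shape(self) -> tuple[int, int, int]:
        return (self.x.size - 1, self.y.size - 1, self.z.size - 1)

    @property
    def n_nodes(self) -> int:
        return self.x.size * self.y.size * self.z.size

    @property
    def n_cells(self) -> int:
        ncx, ncy, ncz = self.cell_shape
        return ncx * ncy * ncz

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.x)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.y)

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z)

    def cell_volumes(self) -> np.ndarray:
        """Per-cell volumes in m^3, shape ``cell_shape``."""
        return (
            self.dx[:, None, None] * self.dy[None, :, None] * self.dz[None, None, :]
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cx = 0.5 * (self.x[:-1] + self.x[1:])
        cy = 0.5 * (self.y[:-1] + self.y[1:])
        cz = 0.5 * (self.z[:-1] + self.z[1:])
        return cx, cy, cz

    def conductive_mask(self) -> np.ndarray:
        """Boolean per-cell mask of current-carrying cells."""
        mask = np.zeros(self.cell_shape, dtype=bool)
        for lab in CONDUCTIVE_LABELS:
            mask |= self.labels == lab
        return mask

    def label_counts(self) -> dict[Label, int]:
        return {lab: int(np.count_nonzero(self.labels == lab)) for lab in Label}

    def boundary_face_counts(self) -> dict[str, int]:
        """Counts of tagged boundary faces.

        ELECTRODE_DIRICHLET: z-faces at the electrode-tissue contact disk;
        PATCH_DIRICHLET: exterior z_max faces of PATCH cells (slab) or the
        staircase ground faces (oracle geometry); INSULATED: every other
        exterior face of the conductive region.
        """
        cond = self.conductive_mask()
        n_exterior = _exterior_face_count(cond)
        n_el = int(self.meta.get("n_electrode_faces", 0))
        n_patch = int(self.meta.get("n_patch_faces", 0))
        return {
            "ELECTRODE_DIRICHLET": n_el,
            "PATCH_DIRICHLET": n_patch,
            "INSULATED": max(n_exterior - n_el - n_patch, 0),
        }


def _exterior_face_count(cond: np.ndarray) -> int:
    """Number of faces between a conductive cell and non-conductive space."""
    total = 0
    for axis in range(3):
        a = np.swapaxes(cond, 0, axis)
        interior = a[:-1] != a[1:]
        total += int(interior.sum())
        total += int(a[0].sum()) + int(a[-1].sum())
    return total


# ---------------------------------------------------------------------------
# graded 1-D axes
# ---------------------------------------------------------------------------


def graded_axis(
    fine_lo: float,
    fine_hi: float,
    h: float,
    grading: float,
    domain_lo: float,
    domain_hi: float,
) -> np.ndarray:
    """1-D node coordinates: uniform spacing ``h`` on [fine_lo, fine_hi],
    geometric coarsening by ``grading`` outward to the domain bounds.

    The outermost cell on each side is stretched or split so the axis lands
    exactly on the domain boundary. Deterministic (no randomness).
    """
    if grading < 1.0:
        raise GeometryConfigError("grading factor must be >= 1")
    if not (domain_lo <= fine_lo < fine_hi <= domain_hi):
        raise GeometryConfigError("fine region must lie within the domain")
    n_fine = max(1, int(round((fine_hi - fine_lo) / h)))
    fine = np.linspace(fine_lo, fine_hi, n_fine + 1)

    def grade_out(start: float, bound: float, direction: float) -> list[float]:
        pts: list[float] = []
        pos = start
        step = h
        remaining = abs(bound - start)
        while remaining > 1e-12:
            step = min(step * grading, remaining)
            # avoid a sliver cell at the boundary
            if remaining - step < 0.25 * step:
                step = remaining
            pos = pos + direction * step
            remaining = abs(bound - pos)
            pts.append(pos)
        return pts

    left = grade_out(fine_lo, domain_lo, -1.0)[::-1]
    right = grade_out(fine_hi, domain_hi, +1.0)
    return np.array(left + list(fine) + right)


# ---------------------------------------------------------------------------
# slab geometry (synthetic open-chest epicardial setup)
# ---------------------------------------------------------------------------


def build_slab_geometry(
    tissue: TissueGeometrySpec,
    electrode: ElectrodeSpec,
    fine_resolution_mm: float = 0.35,
    grading_factor: float = 1.3,
    lateral_resolution_mm: float | None = None,
    fine_halfwidth_x_mm: float | None = None,
    fine_halfwidth_y_mm: float | None = None,
    fine_depth_mm: float | None = None,
) -> LabeledGrid:
    """Build the labeled slab domain for the epicardial ablation setup.

    The electrode tip end is flush with the epicardial plane (z = 0), its
    axis along z; the slab (MYOCARDIUM) occupies 0 < z < wall; BLOOD lies
    beneath it, TORSO below that; the grounded PATCH occupies the last cell
    layer before the far face within its footprint. Cells above z = 0 are
    ELECTRODE within the tip radius and OUTSIDE (open air) elsewhere.

    ``fine_resolution_mm`` is the depth (z) resolution through the wall;
    ``lateral_resolution_mm`` (default: the same) the in-plane resolution.
    Both must resolve the contact: <= electrode diameter / 4. Lesion
    morphometry reads widths along x on the y = 0 plane, so the fine x span
    (default 10 mm) is wider than the fine y span (default electrode radius
    + 2.5 mm); beyond the fine box the spacing coarsens geometrically by
    ``grading_factor`` out to the torso boundary.
    """
    if lateral_resolution_mm is None:
        lateral_resolution_mm = fine_resolution_mm
    for res in (fine_resolution_mm, lateral_resolution_mm):
        if res > electrode.diameter_mm / 4.0 + 1e-12:
            raise ValueError(
                "grid resolution must be <= electrode diameter / 4 "
                f"({electrode.diameter_mm / 4.0:.4g} mm) to resolve the contact"
            )
    if grading_factor < 1.0:
        raise ValueError("grading_factor must be >= 1")
    tx, ty, tz = tissue.torso_extent_mm
    if electrode.diameter_mm >= min(tx, ty):
        raise GeometryConfigError(
            "electrode footprint larger than the torso cross-section"
        )

    h = fine_resolution_mm
    hl = lateral_resolution_mm
    r_el = electrode.radius_mm
    if fine_halfwidth_x_mm is None:
        fine_halfwidth_x_mm = min(10.0, 0.45 * tx)
    if fine_halfwidth_y_mm is None:
        fine_halfwidth_y_mm = min(r_el + 2.5, 0.45 * ty)
    if fine_depth_mm is None:
        fine_depth_mm = min(tissue.wall_thickness_mm + h,
                            0.9 * (tissue.wall_thickness_mm
                                   + tissue.blood_pool_depth_mm))

    x = graded_axis(-fine_halfwidth_x_mm, fine_halfwidth_x_mm, hl,
                    grading_factor, -tx / 2.0, tx / 2.0) * MM
    y = graded_axis(-fine_halfwidth_y_mm, fine_halfwidth_y_mm, hl,
                    grading_factor, -ty / 2.0, ty / 2.0) * MM
    # z: electrode region above the plane (coarser is fine, it only labels),
    # fine through the wall, graded down to the far face
    z_above = graded_axis(-electrode.tip_length_mm, 0.0,
                          max(h, electrode.tip_length_mm / 7.0), grading_factor,
                          -electrode.tip_length_mm, 0.0)
    z_below = graded_axis(0.0, fine_depth_mm, h, grading_factor, 0.0, tz)
    z = np.concatenate([z_above[:-1], z_below]) * MM
    # ensure material interfaces fall on grid planes
    z = _insert_planes(z, [tissue.wall_thickness_mm * MM,
                           (tissue.wall_thickness_mm
                            + tissue.blood_pool_depth_mm) * MM])

    ncx, ncy, ncz = x.size - 1, y.size - 1, z.size - 1
    cx, cy, cz = (0.5 * (x[:-1] + x[1:]), 0.5 * (y[:-1] + y[1:]),
                  0.5 * (z[:-1] + z[1:]))
    labels = np.full((ncx, ncy, ncz), Label.TORSO, dtype=np.int8)

    wall = tissue.wall_thickness_mm * MM
    blood_hi = wall + tissue.blood_pool_depth_mm * MM
    in_wall = (cz > 0) & (cz < wall)
    in_blood = (cz >= wall) & (cz < blood_hi)
    labels[:, :, in_wall] = Label.MYOCARDIUM
    labels[:, :, in_blood] = Label.BLOOD

    above = cz < 0
    rr2 = cx[:, None] ** 2 + cy[None, :] ** 2
    in_tip = rr2 <= (r_el * MM) ** 2
    for k in np.nonzero(above)[0]:
        labels[:, :, k] = np.where(in_tip, Label.ELECTRODE, Label.OUTSIDE)

    # patch: last cell layer in z within the footprint
    px, py = tissue.patch_size_mm
    on_patch = (np.abs(cx)[:, None] <= px / 2.0 * MM + 1e-12) & (
        np.abs(cy)[None, :] <= py / 2.0 * MM + 1e-12
    )
    labels[:, :, -1] = np.where(on_patch, Label.PATCH, labels[:, :, -1])

    # Dirichlet node masks
    nx_, ny_, nz_ = x.size, y.size, z.size
    electrode_nodes = np.zeros((nx_, ny_, nz_), dtype=bool)
    k0 = int(np.searchsorted(z, 0.0 - 1e-15))  # node index of the z=0 plane
    node_r2 = x[:, None] ** 2 + y[None, :] ** 2
    contact = node_r2 <= (r_el * MM) ** 2 + 1e-18
    electrode_nodes[:, :, k0] = contact

    patch_nodes = np.zeros((nx_, ny_, nz_), dtype=bool)
    patch_cells_xy = on_patch
    # nodes of patch cells on the far face
    pc = np.zeros((nx_, ny_), dtype=bool)
    ii, jj = np.nonzero(patch_cells_xy)
    for di in (0, 1):
        for dj in (0, 1):
            pc[ii + di, jj + dj] = True
    patch_nodes[:, :, -1] = pc

    n_el_faces = int(np.count_nonzero(in_tip & (labels[:, :, k0] == Label.MYOCARDIUM)))
    n_patch_faces = int(np.count_nonzero(patch_cells_xy))

    grid = LabeledGrid(
        x=x, y=y, z=z, labels=labels,
        electrode_nodes=electrode_nodes, patch_nodes=patch_nodes,
        wall_thickness_mm=tissue.wall_thickness_mm,
        fine_resolution_mm=fine_resolution_mm,
        meta={
            "kind": "slab",
            "tissue": tissue,
            "electrode": electrode,
            "grading_factor": grading_factor,
            "lateral_resolution_mm": lateral_resolution_mm,
            "n_electrode_faces": n_el_faces,
            "n_patch_faces": n_patch_faces,
        },
    )
    _check_dirichlet_presence(grid)
    return grid


def _insert_planes(z: np.ndarray, planes: list[float]) -> np.ndarray:
    """Snap-or-insert the given coordinates as grid planes."""
    z = z.copy()
    for p in planes:
        i = int(np.argmin(np.abs(z - p)))
        local_h = min(
            z[i] - z[i - 1] if i > 0 else np.inf,
            z[i + 1] - z[i] if i + 1 < z.size else np.inf,
        )
        if abs(z[i] - p) <= 0.3 * local_h and 0 < i < z.size - 1:
            z[i] = p
        elif abs(z[i] - p) > 1e-15:
            z = np.sort(np.append(z, p))
    return z


def _check_dirichlet_presence(grid: LabeledGrid) -> None:
    if not grid.electrode_nodes.any():
        raise GeometryConfigError("no electrode Dirichlet nodes were created")
    if not grid.patch_nodes.any():
        raise GeometryConfigError("no patch (ground) Dirichlet nodes were created")


# ---------------------------------------------------------------------------
# hemispherical-electrode oracle geometry
# ---------------------------------------------------------------------------


def build_hemisphere_oracle_geometry(
    electrode_radius_mm: float,
    domain_radius_mm: float,
    resolution_mm: float,
    grading_factor: float = 1.4,
    fine_radius_mm: float | None = None,
    ground_mode: str = "far_field",
    refinement_level: int = 0,
) -> LabeledGrid:
    """Hemispherical electrode (radius a) on a homogeneous half-space with
    an outer hemispherical boundary at radius R.

    ``ground_mode='far_field'`` (default, used for verification): the outer
    boundary nodes carry the analytic far-field profile V*a/r evaluated at
    each node's own radius, so the infinite-half-space closed form
    phi = V*a/r, E = V*a/r^2, I = 2*pi*sigma*a*V is the exact continuum
    solution and discretization error is confined to the electrode
    neighbourhood. ``ground_mode='grounded'`` instead grounds the outer
    shell at 0 V (the physical analog of a distant dispersive patch), for
    which the exact solution is phi = V*(a/r - a/R)/(1 - a/R).

    Cells entirely inside the electrode sphere are ELECTRODE; active tissue
    (a single MYOCARDIUM label) fills the rest up to R; cells entirely
    beyond R are OUTSIDE. Dirichlet electrode nodes are the nodes with
    r <= a; outer Dirichlet nodes are the staircase shell at r >= R touching
    an active cell. All other exterior faces (the z = 0 symmetry plane) are
    insulated.

    ``refinement_level`` bisects every grid cell that many times after the
    graded axes are laid out — global uniform refinement, the mesh family a
    convergence study requires (refining only the fine region would leave
    the graded-region truncation error untouched).
    """
    if ground_mode not in ("far_field", "grounded"):
        raise GeometryConfigError("ground_mode must be 'far_field' or 'grounded'")
    if refinement_level < 0:
        raise GeometryConfigError("refinement_level must be >= 0")
    a, R, h = electrode_radius_mm, domain_radius_mm, resolution_mm
    if a <= 0 or R <= 0 or h <= 0:
        raise GeometryConfigError("radii and resolution must be positive")
    if not a < R / 5.0:
        raise ValueError(
            "electrode_radius_mm must be < domain_radius_mm / 5 for the "
            "far-field oracle to be meaningful"
        )
    if h > a / 4.0 + 1e-12:
        raise ValueError("resolution_mm must be <= electrode_radius_mm / 4")
    if fine_radius_mm is None:
        fine_radius_mm = min(2.5 * a, R / 2.0)

    pad = R + 2.5 * h * grading_factor ** 3
    x = graded_axis(-fine_radius_mm, fine_radius_mm, h, grading_factor,
                    -pad, pad) * MM
    y = x.copy()
    zax = graded_axis(0.0, fine_radius_mm, h, grading_factor, 0.0, pad) * MM
    for _ in range(refinement_level):
        x = _bisect_axis(x)
        y = _bisect_axis(y)
        zax = _bisect_axis(zax)
        h = h / 2.0

    # classify cells by full-corner containment: a cell is ELECTRODE only if
    # entirely inside the electrode sphere and OUTSIDE only if entirely
    # beyond the ground radius, so cells straddling either sphere stay
    # conductive and the solver's cut-edge correction places the exact
    # spherical boundary through them
    ax2 = np.maximum(x[:-1] ** 2, x[1:] ** 2)
    ay2 = np.maximum(y[:-1] ** 2, y[1:] ** 2)
    az2 = np.maximum(zax[:-1] ** 2, zax[1:] ** 2)
    r2_corner_max = ax2[:, None, None] + ay2[None, :, None] + az2[None, None, :]
    ix2 = np.minimum(x[:-1] ** 2, x[1:] ** 2)
    iy2 = np.minimum(y[:-1] ** 2, y[1:] ** 2)
    iz2 = np.minimum(zax[:-1] ** 2, zax[1:] ** 2)
    r2_corner_min = ix2[:, None, None] + iy2[None, :, None] + iz2[None, None, :]
    labels = np.full(r2_corner_max.shape, Label.MYOCARDIUM, dtype=np.int8)
    labels[r2_corner_max <= (a * MM) ** 2] = Label.ELECTRODE
    labels[r2_corner_min >= (R * MM) ** 2] = Label.OUTSIDE

    r_node = np.sqrt(
        x[:, None, None] ** 2 + y[None, :, None] ** 2 + zax[None, None, :] ** 2
    )
    active = labels == Label.MYOCARDIUM
    touches_active = _nodes_touching(active)
    electrode_nodes = (r_node <= a * MM + 1e-15) & touches_active
    patch_nodes = (r_node >= R * MM - 1e-15) & touches_active

    # the electrode sphere always gets the cut-edge correction; the outer
    # shell only when it is an equipotential (grounded) surface — in
    # far-field mode each outer node carries its own exact value instead
    spheres = [{"nodes": "electrode", "radius_m": a * MM, "inside": True}]
    patch_profile = None
    if ground_mode == "grounded":
        spheres.append({"nodes": "patch", "radius_m": R * MM, "inside": False})
    else:
        with np.errstate(divide="ignore"):
            coeff = np.where(r_node > 0, (a * MM) / np.maximum(r_node, a * MM),
                             1.0)
        patch_profile = np.where(patch_nodes, coeff, 0.0)

    grid = LabeledGrid(
        x=x, y=y, z=zax, labels=labels,
        electrode_nodes=electrode_nodes, patch_nodes=patch_nodes,
        patch_potential_per_volt=patch_profile,
        wall_thickness_mm=None,
        fine_resolution_mm=h,
        meta={
            "kind": "hemisphere_oracle",
            "electrode_radius_mm": a,
            "domain_radius_mm": R,
            "grading_factor": grading_factor,
            "ground_mode": ground_mode,
            # exact spherical Dirichlet surfaces for the embedded-boundary
            # (cut-edge) conductance correction in the solver
            "embedded_spheres": tuple(spheres),
            "n_electrode_faces": int(_dirichlet_face_count(active, electrode_nodes)),
            "n_patch_faces": int(_dirichlet_face_count(active, patch_nodes)),
        },
    )
    _check_dirichlet_presence(grid)
    return grid


def _bisect_axis(nodes: np.ndarray) -> np.ndarray:
    """Insert the midpoint of every cell (global uniform refinement)."""
    mid = 0.5 * (nodes[:-1] + nodes[1:])
    out = np.empty(nodes.size + mid.size)
    out[0::2] = nodes
    out[1::2] = mid
    return out


def _nodes_touching(cells: np.ndarray) -> np.ndarray:
    """Boolean node mask: node is a corner of at least one True cell."""
    nx_, ny_, nz_ = (s + 1 for s in cells.shape)
    out = np.zeros((nx_, ny_, nz_), dtype=bool)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                out[di:di + cells.shape[0],
                    dj:dj + cells.shape[1],
                    dk:dk + cells.shape[2]] |= cells
    return out


def _dirichlet_face_count(active_cells: np.ndarray, nodes: np.ndarray) -> int:
    """Approximate count of active-cell faces whose 4 nodes are all Dirichlet."""
    total = 0
    nmask = nodes
    # x-faces
    fx = (nmask[:, :-1, :-1] & nmask[:, 1:, :-1]
          & nmask[:, :-1, 1:] & nmask[:, 1:, 1:])
    fy = (nmask[:-1, :, :-1] & nmask[1:, :, :-1]
          & nmask[:-1, :, 1:] & nmask[1:, :, 1:])
    fz = (nmask[:-1, :-1, :] & nmask[1:, :-1, :]
          & nmask[:-1, 1:, :] & nmask[1:, 1:, :])
    for f, axis in ((fx, 0), (fy, 1), (fz, 2)):
        adj = np.zeros_like(f, dtype=bool)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        adj[tuple(sl_lo)] |= active_cells
        adj[tuple(sl_hi)] |= active_cells
        total += int((f & adj).sum())
    return total
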