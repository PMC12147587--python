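"""Irreversible-electroporation lesion extraction and morphometry.

A lesion is the set of myocardial cells whose field magnitude meets or
exceeds a lethal threshold (V/cm). Depth D and width W are measured on the
cross-sectional plane through the catheter axis at the electrode midpoint,
mirroring standard histological assessment: D is the maximum extent of the
lesion into the wall below the epicardial plane, W the maximum lateral
extent over all depths on that plane, and the anisotropy ratio AR = W / D
characterises lesion shape for nontransmural lesions (AR is biased by the
wall thickness once transmurality is reached, where width alone is
comparable). Extents are measured between cell faces (half-open cell
convention), so a single-cell lesion has the extent of that cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import MM, Label, LabeledGrid


@dataclass(frozen=True)
class LesionMetrics:
    """Morphometry of one lesion at one (voltage, threshold) pair.

    ``anisotropy_ratio_AR`` is NaN (undefined) for empty or zero-depth
    lesions, never 0. ``depth_of_max_width_mm`` is the depth of the shallow
    face of the cell row achieving the maximum width, ties broken toward the
    surface. For transmural lesions depth equals the wall thickness.
    """

    threshold_V_per_cm: float
    depth_D_mm: float
    width_W_mm: float
    anisotropy_ratio_AR: float
    transmural: bool
    depth_of_max_width_mm: float
    lesion_volume_mm3: float
    empty: bool

    @property
    def ar_defined(self) -> bool:
        return not math.isnan(self.anisotropy_ratio_AR)


def ire_region(
    E_per_cell: np.ndarray, grid: LabeledGrid, threshold_V_per_cm: float
) -> np.ndarray:
    """Binary lesion mask: myocardium cells with E >= threshold.

    Cells of any other label are always False. Masks nest: a higher
    threshold's mask is a subset of a lower one's.
    """
    if threshold_V_per_cm <= 0:
        raise ValueError("lethal threshold must be positive (V/cm)")
    E = np.asarray(E_per_cell, dtype=float)
    if E.shape != grid.cell_shape:
        raise ValueError("E_per_cell shape does not match grid cells")
    return (grid.labels == Label.MYOCARDIUM) & (E >= threshold_V_per_cm)


def _midplane_columns(grid: LabeledGrid) -> list[int]:
    """Indices of the cell column(s) straddling the catheter plane y = 0.

    When y = 0 is a grid node (symmetric grids), the two adjacent columns
    are both part of the measurement plane.
    """
    y = grid.y
    cols = [j for j in range(y.size - 1) if y[j] <= 0.0 <= y[j + 1]]
    if not cols:
        raise ValueError(
            "measurement-plane misconfiguration: the catheter plane y = 0 "
            "does not intersect the grid"
        )
    return cols


def measure_lesion(
    mask: np.ndarray, grid: LabeledGrid, wall_thickness_mm: float | None = None
) -> LesionMetrics:
    """Measure lesion morphometry on the mid-catheter plane.

    Depth, width and depth-of-max-width come from the plane section through
    the catheter axis; lesion volume integrates the full 3-D mask. An empty
    mask yields D = W = 0 with AR undefined (NaN).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.cell_shape:
        raise ValueError("mask shape does not match grid cells")
    if wall_thickness_mm is None:
        wall_thickness_mm = grid.wall_thickness_mm

    volume_mm3 = float((grid.cell_volumes()[mask]).sum() / MM**3)

    cols = _midplane_columns(grid)
    plane = np.zeros((mask.shape[0], mask.shape[2]), dtype=bool)
    for j in cols:
        plane |= mask[:, j, :]

    # threshold used for "empty": the plane section (the assessed section)
    if not plane.any():
        return LesionMetrics(
            threshold_V_per_cm=float("nan"),
            depth_D_mm=0.0,
            width_W_mm=0.0,
            anisotropy_ratio_AR=float("nan"),
            transmural=False,
            depth_of_max_width_mm=float("nan"),
            lesion_volume_mm3=volume_mm3,
            empty=True,
        )

    x, z = grid.x, grid.z
    k0 = int(np.searchsorted(z, 0.0 - 1e-15))  # node index of epicardial plane

    # depth: deepest masked cell face below z = 0 on the plane
    rows = np.nonzero(plane.any(axis=0))[0]
    depth_m = float(z[rows.max() + 1])  # deep face of deepest masked row
    depth_mm = depth_m / MM

    # width per row: face-based lateral extent
    width_mm = 0.0
    depth_of_max_width_mm = float("nan")
    for k in rows:
        ii = np.nonzero(plane[:, k])[0]
        w = float(x[ii.max() + 1] - x[ii.min()]) / MM
        row_depth_mm = max(float(z[k]) / MM, 0.0)  # shallow face of the row
        if w > width_mm + 1e-12:
            width_mm = w
            depth_of_max_width_mm = row_depth_mm
        elif abs(w - width_mm) <= 1e-12 and row_depth_mm < depth_of_max_width_mm:
            depth_of_max_width_mm = row_depth_mm  # tie toward the surface

    transmural = False
    if wall_thickness_mm is not None:
        transmural = depth_mm >= wall_thickness_mm - 1e-9
        if transmural:
            depth_mm = float(wall_thickness_mm)

    ar = width_mm / depth_mm if depth_mm > 0 else float("nan")
    return LesionMetrics(
        threshold_V_per_cm=float("nan"),
        depth_D_mm=depth_mm,
        width_W_mm=width_mm,
        anisotropy_ratio_AR=ar,
        transmural=transmural,
        depth_of_max_width_mm=depth_of_max_width_mm,
        lesion_volume_mm3=volume_mm3,
        empty=False,
    )


def max_width_at_surface(
    metrics: LesionMetrics, tolerance_mm: float | None = None,
    fine_resolution_mm: float | None = None,
) -> bool:
    """True iff the maximum lesion width occurs at the epicardial surface.

    The default tolerance is one fine-grid cell. Raises on empty lesions.
    """
    if metrics.empty:
        raise ValueError("max_width_at_surface is undefined for an empty lesion")
    if tolerance_mm is None:
        tolerance_mm = fine_resolution_mm if fine_resolution_mm else 0.0
    return metrics.depth_of_max_width_mm <= tolerance_mm + 1e-12
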