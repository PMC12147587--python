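"""Run configuration, pipeline driver, structured outputs, and field export.

The pipeline is fully deterministic: there is no stochastic component
anywhere (geometry, solver, and morphometry are all closed-form given the
configuration), so identical configs produce byte-identical outputs. The
persisted config materialises every default, making runs self-describing.

Outputs: a CSV sweep table (one row per voltage x threshold), a calibration
/ dual-threshold report in both plain text and JSON, a solver-diagnostics
JSON, and optional legacy-VTK ASCII rectilinear-grid volumes (potential,
field magnitude, tissue label, lesion mask) for visualization.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from .conductivity import ConductivityModel
from .field_solver import FieldSolution, SolverConfig
from .geometry import ElectrodeSpec, Label, LabeledGrid, TissueGeometrySpec, \
    build_hemisphere_oracle_geometry, build_slab_geometry
from .lesion_metrics import ire_region
from .sweep_analysis import ExperimentalRange, ThresholdSweepSpec, \
    dual_threshold_report, run_threshold_sweep

log = logging.getLogger("pfalesion")


# ---------------------------------------------------------------------------
# config schema (units are explicit in key names)
# ---------------------------------------------------------------------------


class ElectrodeConfig(BaseModel):
    diameter_mm: float = 8.0 / 3.0
    tip_length_mm: float = 3.5
    orientation: str = "perpendicular"


class GeometryConfig(BaseModel):
    kind: str = "slab"  # 'slab' or 'hemisphere_oracle'
    wall_thickness_mm: float = 10.0
    blood_pool_depth_mm: float = 30.0
    torso_extent_mm: tuple[float, float, float] = (160.0, 120.0, 80.0)
    patch_size_mm: tuple[float, float] = (150.0, 90.0)
    fine_resolution_mm: float = 0.35
    lateral_resolution_mm: float = 0.5
    grading_factor: float = 1.3
    electrode: ElectrodeConfig = Field(default_factory=ElectrodeConfig)
    # hemisphere-oracle parameters
    electrode_radius_mm: float = 1.335
    domain_radius_mm: float = 24.0

    @field_validator("kind")
    @classmethod
    def _kind(cls, v):
        if v not in ("slab", "hemisphere_oracle"):
            raise ValueError("geometry kind must be 'slab' or 'hemisphere_oracle'")
        return v


class ConductivityConfig(BaseModel):
    myocardium_S_per_m: float = 0.20
    blood_S_per_m: float = 0.70
    torso_S_per_m: float = 0.20
    patch_S_per_m: float = 0.20
    sigma_factor: float = 2.5
    E_low_V_per_cm: float = 400.0
    E_high_V_per_cm: float = 800.0
    transition: str = "smoothed_heaviside"


class SolverSettings(BaseModel):
    picard_tolerance: float = 1e-4
    picard_max_iter: int = 50
    relaxation: float = 0.7
    linear_solver_tolerance: float = 1e-8


class SweepConfig(BaseModel):
    threshold_lo_V_per_cm: float = 200.0
    threshold_hi_V_per_cm: float = 1000.0
    threshold_step_V_per_cm: float = 10.0
    voltages_V: tuple[float, ...] = (1000.0, 2000.0)

    @field_validator("threshold_step_V_per_cm")
    @classmethod
    def _step(cls, v):
        if v <= 0:
            raise ValueError("threshold step must be positive")
        return v

    def thresholds(self) -> np.ndarray:
        t = np.arange(self.threshold_lo_V_per_cm,
                      self.threshold_hi_V_per_cm + 1e-9,
                      self.threshold_step_V_per_cm)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("malformed threshold grid (must be increasing)")
        return t


class ExperimentalRangeConfig(BaseModel):
    metric: str
    low_mm: float
    high_mm: float
    transmural_regime: bool = False


class RunConfig(BaseModel):
    """Top-level, schema-validated run configuration.

    The pipeline has no random component; determinism is structural, not
    seeded.
    """

    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    conductivity: ConductivityConfig = Field(default_factory=ConductivityConfig)
    solver: SolverSettings = Field(default_factory=SolverSettings)
    sweep: SweepConfig = Field(default_factory=SweepConfig)
    experimental_ranges: tuple[ExperimentalRangeConfig, ...] = ()
    output_dir: str = "pfalesion_output"
    export_fields: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        """Persist with every default materialised (self-describing run)."""
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh,
                           sort_keys=True)


# ---------------------------------------------------------------------------
# config -> domain objects
# ---------------------------------------------------------------------------


def build_grid(cfg: GeometryConfig) -> LabeledGrid:
    if cfg.kind == "hemisphere_oracle":
        return build_hemisphere_oracle_geometry(
            electrode_radius_mm=cfg.electrode_radius_mm,
            domain_radius_mm=cfg.domain_radius_mm,
            resolution_mm=cfg.fine_resolution_mm,
        )
    tissue = TissueGeometrySpec(
        wall_thickness_mm=cfg.wall_thickness_mm,
        blood_pool_depth_mm=cfg.blood_pool_depth_mm,
        torso_extent_mm=tuple(cfg.torso_extent_mm),
        patch_size_mm=tuple(cfg.patch_size_mm),
    )
    electrode = ElectrodeSpec(
        diameter_mm=cfg.electrode.diameter_mm,
        tip_length_mm=cfg.electrode.tip_length_mm,
        orientation=cfg.electrode.orientation,
    )
    return build_slab_geometry(
        tissue, electrode,
        fine_resolution_mm=cfg.fine_resolution_mm,
        lateral_resolution_mm=cfg.lateral_resolution_mm,
        grading_factor=cfg.grading_factor,
    )


def build_conductivity_model(cfg: ConductivityConfig) -> ConductivityModel:
    return ConductivityModel(
        sigma0={
            Label.MYOCARDIUM: cfg.myocardium_S_per_m,
            Label.BLOOD: cfg.blood_S_per_m,
            Label.TORSO: cfg.torso_S_per_m,
            Label.PATCH: cfg.patch_S_per_m,
        },
        sigma_factor=cfg.sigma_factor,
        E_low_V_per_cm=cfg.E_low_V_per_cm,
        E_high_V_per_cm=cfg.E_high_V_per_cm,
        transition=cfg.transition,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig | str | Path,
                 output_dir: str | Path | None = None) -> dict:
    """Run geometry -> solve -> sweep -> calibration and write the bundle.

    Returns a dict with the sweep result, reports, diagnostics and paths.
    Raises before any compute on invalid configuration; non-convergence of
    any solve raises SweepConvergenceError (surfaced by the CLI as a nonzero
    exit).
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    thresholds = config.sweep.thresholds()  # validates before compute
    grid = build_grid(config.geometry)
    model = build_conductivity_model(config.conductivity)
    solver = SolverConfig(
        picard_tolerance=config.solver.picard_tolerance,
        picard_max_iter=config.solver.picard_max_iter,
        relaxation=config.solver.relaxation,
        linear_solver_tolerance=config.solver.linear_solver_tolerance,
    )
    spec = ThresholdSweepSpec(
        thresholds_V_per_cm=tuple(thresholds),
        voltages_V=tuple(config.sweep.voltages_V),
    )
    log.info("grid: %s nodes, %s cells", grid.n_nodes, grid.n_cells)
    result = run_threshold_sweep(grid, model, spec, solver)

    config.to_yaml(out / "config.resolved.yaml")
    table_path = out / "sweep.csv"
    result.table.to_csv(table_path, index=False, float_format="%.6g")

    diagnostics = {
        str(int(v)): {
            "converged": sol.converged,
            "iterations": sol.iterations,
            "final_residual": sol.final_residual,
            "electrode_current_A": sol.electrode_current_A,
            "patch_current_A": sol.patch_current_A,
            "warnings": sol.warnings,
        }
        for v, sol in result.solutions.items()
    }
    (out / "diagnostics.json").write_text(
        json.dumps(diagnostics, indent=2, sort_keys=True) + "\n")

    reports = {}
    ranges = [ExperimentalRange(metric=r.metric, low_mm=r.low_mm,
                                high_mm=r.high_mm,
                                transmural_regime=r.transmural_regime)
              for r in config.experimental_ranges]
    depth_ranges = [r for r in ranges if r.metric == "depth"]
    width_ranges = [r for r in ranges if r.metric == "width"]
    if depth_ranges and width_ranges:
        text_lines, js = [], {}
        for V in spec.voltages_V:
            rep = dual_threshold_report(result, depth_ranges[0],
                                        width_ranges[0], V)
            text_lines.append(rep.summary())
            js[str(int(V))] = {
                "depth_interval_V_per_cm": list(rep.depth_interval.as_tuple()),
                "width_interval_V_per_cm": list(rep.width_interval.as_tuple()),
                "overlap_V_per_cm": list(rep.overlap.as_tuple()),
                "single_threshold_sufficient": rep.single_threshold_sufficient,
            }
            reports[V] = rep
        (out / "calibration_report.txt").write_text("\n".join(text_lines))
        (out / "calibration_report.json").write_text(
            json.dumps(js, indent=2, sort_keys=True) + "\n")

    exported = []
    if config.export_fields:
        for V, sol in result.solutions.items():
            mid_t = float(np.median(thresholds))
            mask = ire_region(sol.E_V_per_cm, grid, mid_t)
            path = out / f"field_{int(V)}V.vtk"
            export_field_volume(sol, grid, path, lesion_mask=mask)
            exported.append(path)

    return {
        "result": result,
        "reports": reports,
        "diagnostics": diagnostics,
        "table_path": table_path,
        "exported": exported,
        "output_dir": out,
    }


# ---------------------------------------------------------------------------
# legacy-VTK ASCII rectilinear-grid export (deterministic text writer)
# ---------------------------------------------------------------------------


def export_field_volume(
    solution: FieldSolution,
    grid: LabeledGrid,
    path: str | Path,
    lesion_mask: np.ndarray | None = None,
) -> Path:
    """Write potential, field magnitude, labels and lesion mask as VTK.

    Legacy VTK ASCII RECTILINEAR_GRID: potential as point data; field
    magnitude (V/cm), tissue label and lesion mask as cell data. The writer
    is deterministic (fixed float format), so re-export is bit-identical.
    """
    if not solution.converged:
        log.warning("exporting a non-converged solution to %s", path)
    path = Path(path)
    nx, ny, nz = grid.node_shape
    mask = (np.zeros(grid.cell_shape, dtype=np.int8) if lesion_mask is None
            else lesion_mask.astype(np.int8))

    def fmt(a):
        return "\n".join(" ".join(f"{v:.9g}" for v in row)
                         for row in np.array_split(a, max(1, a.size // 6)))

    # VTK orders points/cells with x fastest; our arrays are (x, y, z) C-order
    pot = solution.potential.transpose(2, 1, 0).reshape(-1)
    E = solution.E_V_per_cm.transpose(2, 1, 0).reshape(-1)
    lab = grid.labels.transpose(2, 1, 0).reshape(-1)
    msk = mask.transpose(2, 1, 0).reshape(-1)

    lines = [
        "# vtk DataFile Version 3.0",
        "pfalesion field volume",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"X_COORDINATES {nx} double",
        fmt(grid.x),
        f"Y_COORDINATES {ny} double",
        fmt(grid.y),
        f"Z_COORDINATES {nz} double",
        fmt(grid.z),
        f"POINT_DATA {nx * ny * nz}",
        "SCALARS potential_V double 1",
        "LOOKUP_TABLE default",
        fmt(pot),
        f"CELL_DATA {(nx - 1) * (ny - 1) * (nz - 1)}",
        "SCALARS E_V_per_cm double 1",
        "LOOKUP_TABLE default",
        fmt(E),
        "SCALARS tissue_label int 1",
        "LOOKUP_TABLE default",
        fmt(lab),
        "SCALARS lesion_mask int 1",
        "LOOKUP_TABLE default",
        fmt(msk),
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_field_volume(path: str | Path) -> dict:
    """Read back a volume written by :func:`export_field_volume`.

    Minimal reader for round-trip checks of this package's own files.
    """
    tokens = Path(path).read_text().split("\n")
    data: dict = {}
    i = 0

    def read_array(start, count, dtype=float):
        vals: list = []
        j = start
        while len(vals) < count:
            vals.extend(type_cast(tokens[j], dtype))
            j += 1
        return np.array(vals[:count], dtype=dtype), j

    def type_cast(line, dtype):
        return [dtype(tok) for tok in line.split()]

    while i < len(tokens):
        line = tokens[i]
        if line.startswith("DIMENSIONS"):
            nx, ny, nz = (int(v) for v in line.split()[1:])
            data["dims"] = (nx, ny, nz)
        elif line.startswith(("X_COORDINATES", "Y_COORDINATES", "Z_COORDINATES")):
            key = line[0].lower()
            n = int(line.split()[1])
            arr, i = read_array(i + 1, n)
            data[key] = arr
            continue
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            kind = line.split()[2]
            nx, ny, nz = data["dims"]
            count = (nx * ny * nz if not data.get("_cell_section")
                     else (nx - 1) * (ny - 1) * (nz - 1))
            arr, i = read_array(i + 2, count,
                                int if kind == "int" else float)
            shape = ((nz, ny, nx) if not data.get("_cell_section")
                     else (nz - 1, ny - 1, nx - 1))
            data[name] = arr.reshape(shape).transpose(2, 1, 0)
            continue
        elif line.startswith("CELL_DATA"):
            data["_cell_section"] = True
        i += 1
    data.pop("_cell_section", None)
    return data
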