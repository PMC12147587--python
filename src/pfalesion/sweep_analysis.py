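"""Lethal-threshold sweeps, voltage-doubling comparison, and calibration.

The field solution does not depend on the lethal threshold, so a sweep
performs exactly one nonlinear solve per applied voltage and re-thresholds
the stored field map. Calibration inverts the monotone threshold-to-size
curves m(T) against experimentally observed lesion-dimension ranges,
returning the contiguous threshold interval whose predicted sizes fall
inside the range (endpoints refined by linear interpolation between sweep
grid points). The dual-threshold report compares the depth-matching and
width-matching intervals: a single lethal threshold is sufficient only when
they overlap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conductivity import ConductivityModel, conductivity_field
from .field_solver import FieldSolution, SolverConfig, solve_potential
from .geometry import LabeledGrid
from .lesion_metrics import LesionMetrics, ire_region, measure_lesion

SWEEP_COLUMNS = [
    "voltage_V", "threshold_V_per_cm", "depth_D_mm", "width_W_mm",
    "anisotropy_ratio_AR", "transmural", "depth_of_max_width_mm",
    "lesion_volume_mm3", "empty",
]


@dataclass(frozen=True)
class ThresholdSweepSpec:
    """Thresholds (V/cm, strictly increasing) x applied peak voltages (V)."""

    thresholds_V_per_cm: tuple = tuple(np.arange(200.0, 1001.0, 10.0))
    voltages_V: tuple = (1000.0, 2000.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds_V_per_cm, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be positive and strictly increasing")
        if any(v <= 0 for v in self.voltages_V):
            raise ValueError("voltages must be positive")


@dataclass(frozen=True)
class ExperimentalRange:
    """Observed lesion-dimension range (mm) for one metric and regime."""

    metric: str  # 'depth' or 'width'
    low_mm: float
    high_mm: float
    transmural_regime: bool = False

    def __post_init__(self) -> None:
        if self.metric not in ("depth", "width"):
            raise ValueError("metric must be 'depth' or 'width'")
        if not 0 < self.low_mm <= self.high_mm:
            raise ValueError("require 0 < low_mm <= high_mm")


@dataclass
class SweepResult:
    """Lesion metrics over a (voltage, threshold) grid plus solver context."""

    table: pd.DataFrame
    solutions: dict  # voltage -> FieldSolution
    grid: LabeledGrid
    spec: ThresholdSweepSpec

    def at(self, voltage: float) -> pd.DataFrame:
        sub = self.table[self.table["voltage_V"] == voltage]
        if sub.empty:
            raise KeyError(f"voltage {voltage} V not present in sweep")
        return sub.reset_index(drop=True)


class SweepConvergenceError(RuntimeError):
    """A field solve in the sweep failed to converge."""


def metrics_row(
    solution: FieldSolution, grid: LabeledGrid, threshold: float
) -> LesionMetrics:
    """Lesion metrics for one threshold on a stored field solution."""
    mask = ire_region(solution.E_V_per_cm, grid, threshold)
    m = measure_lesion(mask, grid)
    return dataclasses.replace(m, threshold_V_per_cm=float(threshold))


def run_threshold_sweep(
    grid: LabeledGrid,
    model: ConductivityModel,
    sweep: ThresholdSweepSpec,
    solver_config: SolverConfig | None = None,
    allow_nonconverged: bool = False,
    solutions: dict | None = None,
) -> SweepResult:
    """One nonlinear solve per voltage, then metrics per threshold.

    Pre-computed ``solutions`` (voltage -> FieldSolution) are reused, e.g.
    to share solves between analyses. A non-converged solve aborts the sweep
    with diagnostics unless ``allow_nonconverged`` is set.
    """
    base = solver_config or SolverConfig()
    solutions = dict(solutions or {})
    rows = []
    prev: FieldSolution | None = None
    # ascending voltage order lets each solve warm-start from the previous
    # one (fields scale ~linearly with V); metrics rows are emitted in the
    # caller's requested order below
    for V in sorted(sweep.voltages_V):
        sol = solutions.get(V)
        if sol is None:
            cfg = dataclasses.replace(base, applied_voltage_V=float(V))
            sigma_init = phi_init = None
            if prev is not None and prev.converged and prev.applied_voltage_V > 0:
                ratio = float(V) / prev.applied_voltage_V
                sigma_init = conductivity_field(model, grid,
                                                prev.E_V_per_cm * ratio)
                phi_init = prev.potential * ratio
            sol = solve_potential(grid, model, cfg, sigma_init=sigma_init,
                                  phi_init=phi_init)
            solutions[V] = sol
        prev = sol
    for V in sweep.voltages_V:
        sol = solutions[V]
        if not sol.converged and not allow_nonconverged:
            raise SweepConvergenceError(
                f"field solve at {V} V did not converge "
                f"(iterations={sol.iterations}, "
                f"residual={sol.final_residual:.3e}); "
                "pass allow_nonconverged=True to override"
            )
        for T in sweep.thresholds_V_per_cm:
            m = metrics_row(sol, grid, float(T))
            rows.append({
                "voltage_V": float(V),
                "threshold_V_per_cm": float(T),
                "depth_D_mm": m.depth_D_mm,
                "width_W_mm": m.width_W_mm,
                "anisotropy_ratio_AR": m.anisotropy_ratio_AR,
                "transmural": m.transmural,
                "depth_of_max_width_mm": m.depth_of_max_width_mm,
                "lesion_volume_mm3": m.lesion_volume_mm3,
                "empty": m.empty,
            })
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    return SweepResult(table=table, solutions=solutions, grid=grid, spec=sweep)


def voltage_comparison(
    result: SweepResult,
    v_low: float,
    v_high: float,
    threshold_subset: np.ndarray | list | None = None,
) -> pd.DataFrame:
    """Per-threshold percent increase in D and W from v_low to v_high.

    increase = 100 * (m(v_high) - m(v_low)) / m(v_low). Depth increases are
    flagged invalid where either lesion is transmural (depth saturated by
    the wall); rows with an empty lesion at v_low are flagged, not dropped.
    """
    lo = result.at(v_low).set_index("threshold_V_per_cm")
    hi = result.at(v_high).set_index("threshold_V_per_cm")
    if threshold_subset is None:
        thresholds = lo.index.to_numpy()
    else:
        thresholds = np.asarray(threshold_subset, dtype=float)
        missing = [t for t in thresholds if t not in lo.index]
        if missing:
            raise KeyError(f"thresholds not in sweep: {missing}")
    out = []
    for T in thresholds:
        a, b = lo.loc[T], hi.loc[T]
        empty_low = bool(a["empty"])
        depth_saturated = bool(a["transmural"] or b["transmural"])
        dw = dd = float("nan")
        if not empty_low and a["width_W_mm"] > 0:
            dw = 100.0 * (b["width_W_mm"] - a["width_W_mm"]) / a["width_W_mm"]
        if not empty_low and not depth_saturated and a["depth_D_mm"] > 0:
            dd = 100.0 * (b["depth_D_mm"] - a["depth_D_mm"]) / a["depth_D_mm"]
        out.append({
            "threshold_V_per_cm": float(T),
            "width_increase_pct": dw,
            "depth_increase_pct": dd,
            "depth_saturated": depth_saturated,
            "empty_at_v_low": empty_low,
        })
    return pd.DataFrame(out)


@dataclass(frozen=True)
class ThresholdInterval:
    """Calibrated lethal-threshold interval [t_min, t_max] (V/cm).

    Empty intervals have t_min = t_max = NaN. ``contiguous`` is False when
    the matching set on the sweep grid is a union of disjoint runs (possible
    only for non-monotone size curves); ``segments`` then lists them all.
    """

    t_min_V_per_cm: float
    t_max_V_per_cm: float
    empty: bool
    contiguous: bool = True
    segments: tuple = ()

    def as_tuple(self) -> tuple[float, float]:
        return (self.t_min_V_per_cm, self.t_max_V_per_cm)


def _interp_crossing(t0, t1, m0, m1, target):
    """Threshold where the linearly interpolated m(T) crosses ``target``."""
    if m1 == m0:
        return t0
    return t0 + (target - m0) * (t1 - t0) / (m1 - m0)


def calibrate_threshold(
    result: SweepResult,
    experimental: ExperimentalRange,
    voltage: float,
) -> ThresholdInterval:
    """Thresholds whose predicted metric lies within the experimental range.

    Transmural-regime ranges may only calibrate the lesion width: depth (and
    AR) are biased by the wall thickness once transmurality is reached.
    Nontransmural depth calibration excludes transmural-saturated rows. For
    the nonincreasing m(T) produced by physical sweeps the matching set is a
    contiguous interval; endpoints are refined by linear interpolation of
    m(T) between adjacent sweep grid points. An empty set is a valid result.
    """
    if experimental.transmural_regime and experimental.metric != "width":
        raise ValueError(
            "transmural regime: only width may be calibrated — depth and AR "
            "are biased by the wall thickness once transmurality is reached"
        )
    sub = result.at(voltage)
    col = "depth_D_mm" if experimental.metric == "depth" else "width_W_mm"
    if experimental.metric == "depth" and not experimental.transmural_regime:
        sub = sub[~sub["transmural"].astype(bool)].reset_index(drop=True)
    sub = sub[~sub["empty"].astype(bool)].reset_index(drop=True)
    T = sub["threshold_V_per_cm"].to_numpy()
    m = sub[col].to_numpy()
    if T.size == 0:
        return ThresholdInterval(float("nan"), float("nan"), empty=True)

    lo, hi = experimental.low_mm, experimental.high_mm
    inside = (m >= lo - 1e-12) & (m <= hi + 1e-12)
    if not inside.any():
        return ThresholdInterval(float("nan"), float("nan"), empty=True)

    # contiguous runs of matching grid points
    idx = np.nonzero(inside)[0]
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    runs = np.split(idx, breaks + 1)

    monotone = bool(np.all(np.diff(m) <= 1e-9))
    segments = []
    for run in runs:
        i0, i1 = run[0], run[-1]
        t_lo, t_hi = T[i0], T[i1]
        # refine endpoints by interpolating m(T) toward the range bounds
        if i0 > 0:
            m_prev, m_here = m[i0 - 1], m[i0]
            if m_prev > hi >= m_here:  # nonincreasing entry through 'hi'
                t_lo = _interp_crossing(T[i0 - 1], T[i0], m_prev, m_here, hi)
            elif m_prev < lo <= m_here:  # nondecreasing entry through 'lo'
                t_lo = _interp_crossing(T[i0 - 1], T[i0], m_prev, m_here, lo)
        if i1 < T.size - 1:
            m_here, m_next = m[i1], m[i1 + 1]
            if m_here >= lo > m_next:  # nonincreasing exit through 'lo'
                t_hi = _interp_crossing(T[i1], T[i1 + 1], m_here, m_next, lo)
            elif m_here <= hi < m_next:  # nondecreasing exit through 'hi'
                t_hi = _interp_crossing(T[i1], T[i1 + 1], m_here, m_next, hi)
        segments.append((float(t_lo), float(t_hi)))

    if monotone or len(segments) == 1:
        t_min = segments[0][0]
        t_max = segments[-1][1]
        return ThresholdInterval(t_min, t_max, empty=False, contiguous=True,
                                 segments=tuple(segments))
    return ThresholdInterval(
        segments[0][0], segments[-1][1], empty=False, contiguous=False,
        segments=tuple(segments),
    )


@dataclass(frozen=True)
class DualThresholdReport:
    """Depth- and width-matching intervals and the single-threshold verdict."""

    voltage_V: float
    depth_interval: ThresholdInterval
    width_interval: ThresholdInterval
    overlap: ThresholdInterval
    single_threshold_sufficient: bool

    def summary(self) -> str:
        def fmt(iv: ThresholdInterval) -> str:
            if iv.empty:
                return "empty (no threshold matches)"
            s = f"[{iv.t_min_V_per_cm:.0f}, {iv.t_max_V_per_cm:.0f}] V/cm"
            if not iv.contiguous:
                s += " (non-contiguous)"
            return s

        verdict = (
            "a single lethal threshold is sufficient (intervals overlap)"
            if self.single_threshold_sufficient
            else "a single lethal threshold is INSUFFICIENT to match both "
            "lesion depth and width (intervals are disjoint)"
        )
        return (
            f"Applied peak voltage: {self.voltage_V:.0f} V\n"
            f"Depth-matching thresholds: {fmt(self.depth_interval)}\n"
            f"Width-matching thresholds: {fmt(self.width_interval)}\n"
            f"Overlap: {fmt(self.overlap)}\n"
            f"Verdict: {verdict}\n"
        )


def dual_threshold_report(
    result: SweepResult,
    depth_range: ExperimentalRange,
    width_range: ExperimentalRange,
    voltage: float,
) -> DualThresholdReport:
    """Calibrate depth and width separately and test for a common threshold."""
    div = calibrate_threshold(result, depth_range, voltage)
    wiv = calibrate_threshold(result, width_range, voltage)
    if div.empty or wiv.empty:
        overlap = ThresholdInterval(float("nan"), float("nan"), empty=True)
    else:
        lo = max(div.t_min_V_per_cm, wiv.t_min_V_per_cm)
        hi = min(div.t_max_V_per_cm, wiv.t_max_V_per_cm)
        if lo <= hi:
            overlap = ThresholdInterval(lo, hi, empty=False)
        else:
            overlap = ThresholdInterval(float("nan"), float("nan"), empty=True)
    return DualThresholdReport(
        voltage_V=float(voltage),
        depth_interval=div,
        width_interval=wiv,
        overlap=overlap,
        single_threshold_sufficient=not overlap.empty,
    )
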