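"""Threshold sweeps, voltage comparison, and interval calibration, checked
against closed forms and a brute-force grid-scan calibration oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from pfalesion import (
    ExperimentalRange,
    SweepConvergenceError,
    SweepResult,
    ThresholdSweepSpec,
    calibrate_threshold,
    dual_threshold_report,
    metrics_row,
    run_threshold_sweep,
    voltage_comparison,
)
from pfalesion.sweep_analysis import SWEEP_COLUMNS


def toy_sweep(thresholds, depth_fn, width_fn, voltage=1000.0,
              transmural_fn=None):
    """SweepResult built directly from analytic size curves."""
    rows = []
    for T in thresholds:
        D, W = depth_fn(T), width_fn(T)
        rows.append({
            "voltage_V": voltage, "threshold_V_per_cm": float(T),
            "depth_D_mm": D, "width_W_mm": W,
            "anisotropy_ratio_AR": W / D if D > 0 else math.nan,
            "transmural": bool(transmural_fn(T)) if transmural_fn else False,
            "depth_of_max_width_mm": 0.0,
            "lesion_volume_mm3": D * W,
            "empty": D == 0.0,
        })
    spec = ThresholdSweepSpec(thresholds_V_per_cm=tuple(thresholds),
                              voltages_V=(voltage,))
    return SweepResult(table=pd.DataFrame(rows, columns=SWEEP_COLUMNS),
                       solutions={}, grid=None, spec=spec)


def brute_force_interval(thresholds, values, lo, hi):
    """Grid-scan oracle: matching grid points only, no interpolation."""
    inside = [(t, v) for t, v in zip(thresholds, values) if lo <= v <= hi]
    if not inside:
        return None
    return inside[0][0], inside[-1][0]


class TestThresholdSweepSpec:
    def test_default_grid_matches_explored_range(self):
        spec = ThresholdSweepSpec()
        t = np.asarray(spec.thresholds_V_per_cm)
        assert t[0] == 200.0 and t[-1] == 1000.0
        assert np.allclose(np.diff(t), 10.0)
        assert spec.voltages_V == (1000.0, 2000.0)

    def test_malformed_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSweepSpec(thresholds_V_per_cm=(500.0, 400.0))
        with pytest.raises(ValueError):
            ThresholdSweepSpec(thresholds_V_per_cm=(0.0, 100.0))
        with pytest.raises(ValueError):
            ThresholdSweepSpec(voltages_V=(-5.0,))


class TestRunThresholdSweep:
    def test_oracle_sweep_matches_closed_form_depths(self, oracle_linear_pair):
        from conftest import A_MM, lethal_radius_mm
        grid, model, sols = oracle_linear_pair
        spec = ThresholdSweepSpec(thresholds_V_per_cm=(300.0, 500.0, 800.0),
                                  voltages_V=(1000.0,))
        res = run_threshold_sweep(grid, model, spec, solutions=sols)
        h = grid.fine_resolution_mm
        for _, row in res.at(1000.0).iterrows():
            r_T = lethal_radius_mm(1000.0, A_MM, row.threshold_V_per_cm)
            assert row.depth_D_mm == pytest.approx(r_T, abs=2 * h)

    def test_sweep_rows_reproduce_independent_measurements(
            self, oracle_linear_pair):
        grid, model, sols = oracle_linear_pair
        spec = ThresholdSweepSpec(thresholds_V_per_cm=(400.0, 700.0),
                                  voltages_V=(1000.0, 2000.0))
        res = run_threshold_sweep(grid, model, spec, solutions=sols)
        for V in spec.voltages_V:
            for T in spec.thresholds_V_per_cm:
                m = metrics_row(sols[V], grid, T)
                row = res.table[(res.table.voltage_V == V)
                                & (res.table.threshold_V_per_cm == T)].iloc[0]
                assert row.depth_D_mm == m.depth_D_mm
                assert row.width_W_mm == m.width_W_mm

    def test_nonconverged_solve_aborts_with_diagnostics(self, coarse_slab):
        import dataclasses
        from pfalesion import SolverConfig
        grid, model = coarse_slab
        cfg = SolverConfig(picard_max_iter=1, picard_tolerance=1e-12,
                           adaptive_relaxation=False)
        spec = ThresholdSweepSpec(thresholds_V_per_cm=(500.0,),
                                  voltages_V=(1000.0,))
        with pytest.raises(SweepConvergenceError, match="did not converge"):
            run_threshold_sweep(grid, model, spec, cfg)
        res = run_threshold_sweep(grid, model, spec, cfg,
                                  allow_nonconverged=True)
        assert len(res.table) == 1


class TestVoltageComparison:
    def test_identical_metrics_give_zero_increase(self):
        t = np.arange(200.0, 401.0, 100.0)
        res = toy_sweep(t, lambda T: 1000 / T, lambda T: 2000 / T)
        res2 = toy_sweep(t, lambda T: 1000 / T, lambda T: 2000 / T,
                         voltage=2000.0)
        res.table = pd.concat([res.table, res2.table], ignore_index=True)
        out = voltage_comparison(res, 1000.0, 2000.0)
        assert np.allclose(out.width_increase_pct, 0.0)
        assert np.allclose(out.depth_increase_pct, 0.0)

    def test_oracle_doubling_gives_sqrt2_increase(self, oracle_linear_pair):
        # closed form: r_T grows like sqrt(V), so doubling the voltage
        # increases depth and width by sqrt(2) - 1 = 41.4%
        grid, model, sols = oracle_linear_pair
        spec = ThresholdSweepSpec(thresholds_V_per_cm=(600.0, 800.0),
                                  voltages_V=(1000.0, 2000.0))
        res = run_threshold_sweep(grid, model, spec, solutions=sols)
        out = voltage_comparison(res, 1000.0, 2000.0)
        h = grid.fine_resolution_mm
        for _, row in out.iterrows():
            r1 = res.at(1000.0).set_index("threshold_V_per_cm").loc[
                row.threshold_V_per_cm, "depth_D_mm"]
            tol = 100 * 2 * h / r1  # face-quantization bound on the ratio
            assert row.depth_increase_pct == pytest.approx(41.42, abs=tol)
            assert row.width_increase_pct == pytest.approx(41.42, abs=tol)

    def test_empty_and_saturated_rows_flagged_not_dropped(self):
        t = [100.0, 200.0, 300.0]
        lo = toy_sweep(t, lambda T: 0.0 if T > 250 else 5.0,
                       lambda T: 0.0 if T > 250 else 8.0,
                       transmural_fn=lambda T: T < 150)
        hi = toy_sweep(t, lambda T: 6.0, lambda T: 10.0, voltage=2000.0)
        lo.table = pd.concat([lo.table, hi.table], ignore_index=True)
        out = voltage_comparison(lo, 1000.0, 2000.0)
        assert len(out) == 3
        assert bool(out.loc[out.threshold_V_per_cm == 100.0,
                            "depth_saturated"].iloc[0])
        assert bool(out.loc[out.threshold_V_per_cm == 300.0,
                            "empty_at_v_low"].iloc[0])
        assert math.isnan(out.loc[out.threshold_V_per_cm == 300.0,
                                  "width_increase_pct"].iloc[0])


class TestCalibrateThreshold:
    def test_toy_inverse_curve_inverts_exactly(self):
        # D(T) = 1000 / T over T in [100, 1000]; depth range 2-5 mm maps to
        # thresholds [200, 500]
        t = np.arange(100.0, 1001.0, 10.0)
        res = toy_sweep(t, lambda T: 1000.0 / T, lambda T: 2000.0 / T)
        iv = calibrate_threshold(res, ExperimentalRange("depth", 2.0, 5.0),
                                 1000.0)
        assert not iv.empty
        assert iv.t_min_V_per_cm == pytest.approx(200.0, abs=1.0)
        assert iv.t_max_V_per_cm == pytest.approx(500.0, abs=1.0)
        bf = brute_force_interval(t, 1000.0 / t, 2.0, 5.0)
        assert bf[0] >= iv.t_min_V_per_cm - 10 and bf[1] <= iv.t_max_V_per_cm + 10

    def test_range_covering_everything_returns_full_sweep(self):
        t = np.arange(200.0, 1001.0, 10.0)
        res = toy_sweep(t, lambda T: 1000.0 / T, lambda T: 2000.0 / T)
        iv = calibrate_threshold(res, ExperimentalRange("depth", 0.5, 100.0),
                                 1000.0)
        assert (iv.t_min_V_per_cm, iv.t_max_V_per_cm) == (200.0, 1000.0)

    def test_disjoint_range_returns_empty_interval(self):
        t = np.arange(200.0, 1001.0, 10.0)
        res = toy_sweep(t, lambda T: 1000.0 / T, lambda T: 2000.0 / T)
        iv = calibrate_threshold(res, ExperimentalRange("depth", 50.0, 60.0),
                                 1000.0)
        assert iv.empty

    def test_brute_force_scan_agrees_on_random_monotone_sweeps(self):
        rng = np.random.default_rng(3)
        t = np.arange(200.0, 1001.0, 10.0)
        for _ in range(50):
            scale = rng.uniform(500, 5000)
            res = toy_sweep(t, lambda T: scale / T, lambda T: 2 * scale / T)
            lo = float(rng.uniform(0.5, 10))
            hi = lo + float(rng.uniform(0.1, 10))
            iv = calibrate_threshold(res,
                                     ExperimentalRange("depth", lo, hi), 1000.0)
            bf = brute_force_interval(t, scale / t, lo, hi)
            if bf is None:
                # interpolated endpoints may still catch a sliver between
                # grid points; the reverse (grid hit but empty interval)
                # must never happen
                continue
            assert not iv.empty
            assert iv.t_min_V_per_cm <= bf[0] + 1e-9
            assert iv.t_max_V_per_cm >= bf[1] - 1e-9
            assert iv.t_min_V_per_cm >= bf[0] - 10.0
            assert iv.t_max_V_per_cm <= bf[1] + 10.0

    def test_transmural_regime_forbids_depth_calibration(self):
        t = np.arange(200.0, 301.0, 10.0)
        res = toy_sweep(t, lambda T: 1000.0 / T, lambda T: 2000.0 / T)
        with pytest.raises(ValueError, match="wall"):
            calibrate_threshold(
                res, ExperimentalRange("depth", 2.0, 5.0,
                                       transmural_regime=True), 1000.0)

    def test_non_monotone_curve_flagged_non_contiguous(self):
        t = np.arange(100.0, 501.0, 100.0)
        vals = {100.0: 3.0, 200.0: 8.0, 300.0: 3.0, 400.0: 8.0, 500.0: 3.0}
        res = toy_sweep(t, lambda T: vals[T], lambda T: 2 * vals[T])
        iv = calibrate_threshold(res, ExperimentalRange("depth", 2.0, 4.0),
                                 1000.0)
        assert not iv.empty
        assert not iv.contiguous
        assert len(iv.segments) == 3

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            ExperimentalRange("depth", 5.0, 2.0)
        with pytest.raises(ValueError):
            ExperimentalRange("volume", 1.0, 2.0)


class TestDualThresholdReport:
    def test_disjoint_intervals_mean_single_threshold_insufficient(self):
        t = np.arange(100.0, 1001.0, 10.0)
        # depth matches at low thresholds only, width at high only
        res = toy_sweep(t, lambda T: 1000.0 / T, lambda T: 1200.0 / T)
        rep = dual_threshold_report(
            res,
            ExperimentalRange("depth", 5.0, 8.0),    # T in [125, 200]
            ExperimentalRange("width", 1.5, 2.4),    # T in [500, 800]
            1000.0,
        )
        assert not rep.single_threshold_sufficient
        assert rep.overlap.empty
        assert "INSUFFICIENT" in rep.summary()

    def test_consistent_ranges_on_symmetric_lesion_overlap(self):
        # AR = 2 everywhere: width range = 2 x depth range selects the same
        # thresholds, so one threshold suffices
        t = np.arange(100.0, 1001.0, 10.0)
        res = toy_sweep(t, lambda T: 1000.0 / T, lambda T: 2000.0 / T)
        rep = dual_threshold_report(
            res,
            ExperimentalRange("depth", 2.0, 5.0),
            ExperimentalRange("width", 4.0, 10.0),
            1000.0,
        )
        assert rep.single_threshold_sufficient
        assert rep.overlap.t_min_V_per_cm == pytest.approx(200.0, abs=1.0)
        assert rep.overlap.t_max_V_per_cm == pytest.approx(500.0, abs=1.0)

    def test_empty_width_interval_annotated(self):
        t = np.arange(100.0, 1001.0, 10.0)
        res = toy_sweep(t, lambda T: 1000.0 / T, lambda T: 2000.0 / T)
        rep = dual_threshold_report(
            res,
            ExperimentalRange("depth", 2.0, 5.0),
            ExperimentalRange("width", 100.0, 200.0),
            1000.0,
        )
        assert rep.width_interval.empty
        assert not rep.single_threshold_sufficient
        assert "empty" in rep.summary()
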