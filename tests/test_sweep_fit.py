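"""Sweep orchestration, closed-form law fitting and the 44 degC envelope."""

import numpy as np
import pandas as pd
import pytest

import pulseheat as ph
from pulseheat.errors import FitError, ValidationError
from pulseheat.fixtures import make_synthetic_sweep
from pulseheat.scenario import GridSpec
from pulseheat.sweep_fit import (COL_F, COL_PW, COL_TM, COL_V, FitResult,
                                 find_threshold_contour, fit_power_law,
                                 predict_temperature, run_sweep, surface_44)

A_TM = 1.5e-12  # degC per ns kHz V^2, burst-end law
A_TF = 4.8e-13  # end-of-window law


class TestFit:
    def test_noiseless_recovery_is_exact(self):
        sweep = make_synthetic_sweep(A_TM)
        fit = fit_power_law(sweep)
        assert fit.coefficient == pytest.approx(A_TM, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_coefficient_gives_flat_rows(self):
        sweep = make_synthetic_sweep(0.0)
        assert np.allclose(sweep.table[COL_TM], 37.0)
        assert fit_power_law(sweep).coefficient == pytest.approx(0.0, abs=1e-30)

    def test_noisy_recovery_within_three_standard_errors(self):
        """Monte-Carlo calibration: over 200 seeds the through-origin
        estimator covers the truth within 3 SE essentially always."""
        hits = 0
        for seed in range(200):
            sweep = make_synthetic_sweep(A_TM, noise_sd=0.1, seed=seed)
            x = (sweep.table[COL_PW] * sweep.table[COL_F]
                 * sweep.table[COL_V] ** 2).to_numpy()
            fit = fit_power_law(sweep)
            resid = (sweep.table[COL_TM] - 37.0 - fit.coefficient * x).to_numpy()
            se = np.sqrt(resid @ resid / (len(x) - 1) / (x @ x))
            hits += abs(fit.coefficient - A_TM) <= 3 * se
        assert hits >= 194  # ~99.7% nominal coverage, generous slack

    def test_degenerate_design_rejected(self):
        table = pd.DataFrame({COL_V: [1000.0, 1000.0], COL_PW: [50.0, 50.0],
                              COL_F: [100.0, 100.0], COL_TM: [38.0, 38.0]})
        with pytest.raises(FitError, match="degenerate"):
            fit_power_law(table)


class TestPredict:
    def test_printed_coefficient_reproduces_headline_temperature(self):
        assert predict_temperature(A_TM, 500.0, 1000.0, 4000.0) \
            == pytest.approx(49.0, abs=1e-9)

    def test_zero_width_gives_baseline(self):
        assert predict_temperature(FitResult(2e-12, COL_TM, 1.0), 0.0, 1000.0,
                                   4000.0) == 37.0

    def test_rise_linear_in_burst_count(self):
        one = predict_temperature(A_TM, 500.0, 1000.0, 4000.0, n_bursts=1)
        two = predict_temperature(A_TM, 500.0, 1000.0, 4000.0, n_bursts=2)
        assert two - 37.0 == pytest.approx(2 * (one - 37.0), rel=1e-12)

    def test_burst_count_must_be_positive(self):
        with pytest.raises(ValidationError):
            predict_temperature(A_TM, 500.0, 1000.0, 4000.0, n_bursts=0)


class TestContour:
    def test_closed_form_inversion_of_the_exact_law(self):
        """With the exact law, the 44 degC boundary at (4 kV, 500 ns) sits at
        f = 7 / (a * 500 * 4000^2) ~ 583.3 kHz."""
        sweep = make_synthetic_sweep(A_TM)
        contour = find_threshold_contour(sweep, free=COL_F)
        row = contour[(contour[COL_V] == 4000.0) & (contour[COL_PW] == 500.0)]
        expected = 7.0 / (A_TM * 500.0 * 4000.0**2)
        assert row["status"].item() == "ok"
        assert row["boundary"].item() == pytest.approx(expected, rel=1e-9)

    def test_voltage_axis_interpolates_in_v_squared(self):
        sweep = make_synthetic_sweep(A_TM)
        contour = find_threshold_contour(sweep, free=COL_V)
        row = contour[(contour[COL_PW] == 500.0) & (contour[COL_F] == 1000.0)]
        expected = np.sqrt(7.0 / (A_TM * 500.0 * 1000.0))
        assert row["boundary"].item() == pytest.approx(expected, rel=1e-9)

    def test_unbounded_combinations_reported_not_raised(self):
        sweep = make_synthetic_sweep(1e-16)  # response never reaches 44
        contour = find_threshold_contour(sweep, free=COL_F)
        assert (contour["status"] == "unbounded within sweep range").all()
        assert contour["boundary"].isna().all()

    def test_contour_points_evaluate_at_the_limit(self):
        sweep = make_synthetic_sweep(A_TM)
        contour = find_threshold_contour(sweep, free=COL_F)
        ok = contour[contour["status"] == "ok"]
        t_at_boundary = 37.0 + A_TM * ok[COL_PW] * ok["boundary"] * ok[COL_V] ** 2
        assert np.allclose(t_at_boundary, 44.0, atol=0.2)


class TestSurface:
    def test_exact_law_surface_satisfies_the_invariant(self):
        sweep = make_synthetic_sweep(A_TM)
        vertices, faces = surface_44(sweep)
        assert len(vertices) > 0
        lhs = A_TM * vertices[COL_PW] * vertices[COL_F] * vertices[COL_V] ** 2
        assert np.allclose(lhs, 7.0, rtol=5e-3)
        if len(faces):
            assert faces.min() >= 0 and faces.max() < len(vertices)

    def test_limit_above_sweep_maximum_gives_empty_surface(self):
        sweep = make_synthetic_sweep(1e-16)
        vertices, faces = surface_44(sweep)
        assert len(vertices) == 0
        assert len(faces) == 0


class TestRunSweep:
    def test_two_point_sweep_rows_and_cache(self, default_scenario, coarse_grid,
                                            tmp_path):
        result = run_sweep(default_scenario, voltages=[1000.0, 2000.0],
                           widths=[100.0], rates=[250.0], grid=coarse_grid,
                           t_end=100e-6, cache_dir=tmp_path)
        assert len(result.table) == 2
        assert not result.failed
        assert result.table[COL_TM].iloc[1] > result.table[COL_TM].iloc[0]
        n_cached = len(list(tmp_path.glob("*.json")))
        assert n_cached == 2
        again = run_sweep(default_scenario, voltages=[1000.0, 2000.0],
                          widths=[100.0], rates=[250.0], grid=coarse_grid,
                          t_end=100e-6, cache_dir=tmp_path)
        assert again.table.equals(result.table)
        assert len(list(tmp_path.glob("*.json"))) == n_cached

    def test_impossible_duty_pair_rejected_upfront(self, default_scenario):
        with pytest.raises(ValidationError, match="duty"):
            run_sweep(default_scenario, voltages=[1000.0], widths=[2000.0],
                      rates=[1000.0])

    def test_empty_axis_rejected(self, default_scenario):
        with pytest.raises(ValidationError, match="non-empty"):
            run_sweep(default_scenario, voltages=[], widths=[100.0],
                      rates=[100.0])
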