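"""Pennes bioheat integration: right-hand side, stepping, conservation."""

import dataclasses

import numpy as np
import pytest

import pulseheat as ph
from pulseheat.bioheat import ThermalState, ThermalSystem, pennes_rhs, simulate_burst
from pulseheat.errors import SolverError, ValidationError
from pulseheat.fixtures import make_uniform_block
from pulseheat.meshing import LAB_TUMOR


class TestPennesRhs:
    def test_equilibrium_is_stationary(self):
        """Uniform 37 degC with no metabolic heat: all terms vanish."""
        fx = make_uniform_block(material_key="tumor", initial_t=37.0)
        state = ThermalState(t=0.0, temperature=np.full(fx.grid.shape, 37.0))
        rhs = pennes_rhs(state, fx.grid, fx.scenario)
        assert np.allclose(rhs[np.isfinite(rhs)], 0.0, atol=1e-15)

    def test_metabolic_heating_rate(self):
        """Tumor block, metabolism only: dT/dt = Q_m/(rho c) ~ 8.24e-3 degC/s."""
        fx = make_uniform_block(material_key="tumor", metabolism=True)
        state = ThermalState(t=0.0, temperature=np.full(fx.grid.shape, 37.0))
        rhs = pennes_rhs(state, fx.grid, fx.scenario)
        expected = 42000.0 / (1220.0 * 4180.0)
        assert np.allclose(rhs[np.isfinite(rhs)], expected, rtol=1e-12)
        assert expected == pytest.approx(8.236e-3, rel=1e-3)

    def test_perfusion_relaxation_rate(self):
        """Liver block at 47 degC, perfusion only: dT/dt = -lambda (T - T_b)."""
        fx = make_uniform_block(material_key="liver", initial_t=47.0,
                                perfusion=True)
        state = ThermalState(t=0.0, temperature=np.full(fx.grid.shape, 47.0))
        rhs = pennes_rhs(state, fx.grid, fx.scenario)
        lam = 1000.0 * 4200.0 * 0.0005 / (1080.0 * 3540.0)
        assert lam == pytest.approx(5.49e-4, rel=1e-3)
        assert np.allclose(rhs[np.isfinite(rhs)], -lam * 10.0, rtol=1e-12)

    def test_printed_perfusion_sign_flag_flips_the_term(self):
        fx = make_uniform_block(material_key="liver", initial_t=47.0,
                                perfusion=True)
        flipped = dataclasses.replace(
            fx.scenario,
            solver=dataclasses.replace(fx.scenario.solver,
                                       pennes_printed_sign=True))
        state = ThermalState(t=0.0, temperature=np.full(fx.grid.shape, 47.0))
        rhs_std = pennes_rhs(state, fx.grid, fx.scenario)
        rhs_flip = pennes_rhs(state, fx.grid, flipped)
        good = np.isfinite(rhs_std)
        assert np.allclose(rhs_flip[good], -rhs_std[good], rtol=1e-12)


class TestZeroDimensionalIntegration:
    def test_metabolism_block_matches_closed_form(self):
        fx = make_uniform_block(material_key="tumor", metabolism=True)
        r = simulate_burst(fx.scenario, grid=fx.grid, mode="averaged")
        assert r.peak_tumor_t_final == pytest.approx(fx.expected["t_at_1s"],
                                                     rel=5e-3)

    def test_perfusion_block_matches_closed_form(self):
        fx = make_uniform_block(material_key="liver", initial_t=47.0,
                                perfusion=True)
        r = simulate_burst(fx.scenario, grid=fx.grid, mode="averaged")
        assert r.peak_tumor_t_final == pytest.approx(fx.expected["t_at_1s"],
                                                     rel=5e-3)

    def test_quiescent_block_stays_at_blood_temperature(self):
        fx = make_uniform_block(material_key="tumor", initial_t=37.0)
        r = simulate_burst(fx.scenario, grid=fx.grid, mode="averaged")
        assert r.peak_tumor_t_final == pytest.approx(37.0, abs=1e-9)


class TestBurstSimulation:
    def test_zero_voltage_burst_stays_at_37(self, coarse_grid):
        s = ph.default_scenario(voltage=0.0)
        r = simulate_burst(s, grid=coarse_grid, mode="averaged", t_end=100e-6)
        assert r.peak_tumor_t_burst_end == pytest.approx(37.0, abs=1e-3)
        assert r.porated_voxels == 0

    def test_exact_and_averaged_agree_within_one_pulse(self, default_scenario,
                                                       coarse_grid):
        """Gated and duty-averaged sources deposit the same burst energy; the
        peaks differ by at most one single-pulse temperature increment."""
        re_ = simulate_burst(default_scenario, grid=coarse_grid, mode="exact",
                             t_end=100e-6)
        ra = simulate_burst(default_scenario, grid=coarse_grid, mode="averaged",
                            t_end=100e-6)
        tumor = coarse_grid.material == LAB_TUMOR
        q_peak = re_.field_solution.joule_density[tumor].max()
        rho_c = 1220.0 * 4180.0
        increment = q_peak * default_scenario.protocol.pulse_width * 1e-9 / rho_c
        assert abs(re_.peak_tumor_t_burst_end - ra.peak_tumor_t_burst_end) \
            <= 2 * increment

    def test_averaged_step_size_insensitivity(self, default_scenario, coarse_grid):
        """With the duty-averaged source the burst step only controls the
        (tiny) diffusion error; a 10x finer step moves the peak by < 0.01 degC."""
        fine = dataclasses.replace(
            default_scenario,
            solver=dataclasses.replace(default_scenario.solver,
                                       dt_burst_averaged=1e-7))
        ra = simulate_burst(default_scenario, grid=coarse_grid,
                            mode="averaged", t_end=100e-6)
        rf = simulate_burst(fine, grid=coarse_grid, mode="averaged",
                            t_end=100e-6)
        assert rf.peak_tumor_t_burst_end == pytest.approx(
            ra.peak_tumor_t_burst_end, abs=0.01)

    def test_cooling_phase_peak_monotone_decreasing(self, default_scenario,
                                                    coarse_grid):
        r = simulate_burst(default_scenario, grid=coarse_grid, mode="averaged",
                           t_end=0.2)
        cooling = r.times >= r.t_burst_end
        series = r.max_domain_series[cooling]
        assert np.all(np.diff(series) <= 1e-9)

    def test_times_strictly_increasing(self, default_scenario, coarse_grid):
        r = simulate_burst(default_scenario, grid=coarse_grid, mode="averaged",
                           t_end=0.11)
        assert np.all(np.diff(r.times) > 0)

    def test_unstable_explicit_step_rejected(self, default_scenario, coarse_grid):
        bad = dataclasses.replace(
            default_scenario,
            solver=dataclasses.replace(default_scenario.solver,
                                       dt_burst_averaged=10.0))
        with pytest.raises(SolverError, match="stability"):
            simulate_burst(bad, grid=coarse_grid, mode="averaged", t_end=100e-6)

    def test_unknown_mode_rejected(self, default_scenario, coarse_grid):
        with pytest.raises(ValidationError, match="mode"):
            simulate_burst(default_scenario, grid=coarse_grid, mode="pulsed")


class TestEnergyConservation:
    def test_implicit_phase_conserves_total_heat_without_sources(self):
        """Insulated boundaries, no perfusion/metabolism/Joule: the volume
        integral of rho c T is invariant under backward-Euler stepping."""
        fx = make_uniform_block(material_key="tumor", initial_t=37.0, n=4)
        system = ThermalSystem(fx.scenario, fx.grid)
        rng = np.random.default_rng(7)
        t_vec = 37.0 + 5.0 * rng.random(system.n)  # non-uniform start
        step = system.make_backward_euler(1e-3)
        total0 = float(system.w @ t_vec)
        for _ in range(50):
            t_vec = step(t_vec)
            total = float(system.w @ t_vec)
            assert abs(total - total0) / abs(total0) < 1e-10
            total0 = total
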