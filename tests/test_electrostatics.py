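"""Quasi-static field solver and the electroporation conductivity switch."""

import numpy as np
import pytest

import pulseheat as ph
from pulseheat.electrostatics import (electrode_current, field_and_joule,
                                      porate_fixed_point, solve_potential)
from pulseheat.fixtures import make_slab, make_two_layer_slab
from pulseheat.meshing import (LAB_ELECTRODE_A, LAB_ELECTRODE_B, LAB_LIVER,
                               LAB_TUMOR)
from pulseheat.scenario import ConductivityModel


def _tissue(grid):
    return np.isin(grid.material, (LAB_LIVER, LAB_TUMOR))


class TestSlabClosedForms:
    def test_uniform_slab_linear_potential_and_field(self):
        fx = make_slab(thickness=0.01, voltage=1.0,
                       conductivity_model=ConductivityModel(e_threshold=1e12))
        sigma = np.full(fx.grid.shape, fx.materials["tumor"].sigma_base)
        phi, _ = solve_potential(fx.grid, sigma, 1.0)
        t = _tissue(fx.grid)
        xc = fx.grid.centers[0]
        mask1d = t[:, 0, 0]
        assert np.allclose(phi[:, 0, 0][mask1d],
                           1.0 * (1.0 - xc[mask1d] / 0.01), atol=1e-9)
        e, j, q = field_and_joule(phi, fx.grid, sigma)
        assert np.allclose(e[t], 100.0, rtol=1e-3)  # |E| = V/d = 100 V/m
        assert np.allclose(q[t], sigma[t] * 100.0**2, rtol=1e-3)

    def test_two_layer_field_ratio_from_current_continuity(self):
        fx = make_two_layer_slab()
        fs = porate_fixed_point(fx.grid, fx.materials, fx.conductivity_model,
                                fx.voltage, 37.0)
        # away from the interface cell the per-layer field is uniform
        lab = fx.grid.material[:, 0, 0]
        e = fs.e_magnitude[:, 0, 0]
        e1 = e[lab == LAB_LIVER][:-1]
        e2 = e[lab == LAB_TUMOR][1:-1]
        assert np.allclose(e1, fx.expected["e_layer1"], rtol=1e-9)
        assert np.allclose(e2, fx.expected["e_layer2"], rtol=1e-9)
        assert e1.mean() / e2.mean() == pytest.approx(2.0, rel=1e-9)

    def test_zero_voltage_gives_zero_potential(self):
        fx = make_slab(voltage=0.0)
        sigma = np.full(fx.grid.shape, 0.1)
        phi, _ = solve_potential(fx.grid, sigma, 0.0)
        assert np.all(phi == 0.0)

    def test_joule_density_formula_and_scaling(self):
        """Q = sigma |E|^2, so doubling the voltage quadruples Q."""
        fx = make_slab(thickness=0.0054, voltage=100.0)
        sigma = np.full(fx.grid.shape, 0.426)
        phi1, _ = solve_potential(fx.grid, sigma, 100.0)
        phi2, _ = solve_potential(fx.grid, sigma, 200.0)
        t = _tissue(fx.grid)
        _, _, q1 = field_and_joule(phi1, fx.grid, sigma)
        e2, j2, q2 = field_and_joule(phi2, fx.grid, sigma)
        assert np.allclose(q2[t], 4.0 * q1[t], rtol=1e-9)
        assert np.allclose(q2[t], sigma[t] * e2[t] ** 2, rtol=1e-12)
        assert np.allclose(j2[t], sigma[t] * e2[t], rtol=1e-12)


class TestPorationSwitch:
    def test_above_threshold_slab_porates_everywhere(self):
        fx = make_slab(thickness=0.0054, voltage=540.0)  # 1000 V/cm
        fs = porate_fixed_point(fx.grid, fx.materials, fx.conductivity_model,
                                fx.voltage, 37.0)
        t = _tissue(fx.grid)
        assert fs.porated[t].all()
        assert np.allclose(fs.sigma_effective[t], fx.expected["sigma"])
        assert np.allclose(fs.joule_density[t], fx.expected["q_density"],
                           rtol=1e-3)
        # the switch leaves a uniform field unchanged
        assert np.allclose(fs.e_magnitude[t], fx.expected["e_magnitude"],
                           rtol=1e-3)

    def test_below_threshold_slab_stays_unporated(self):
        fx = make_slab(thickness=0.0054, voltage=400.0)  # ~741 V/cm
        fs = porate_fixed_point(fx.grid, fx.materials, fx.conductivity_model,
                                fx.voltage, 37.0)
        assert not fx.expected["porated"]
        assert not fs.porated.any()
        assert fs.n_iterations == 1

    def test_poration_mask_never_touches_hardware(self, coarse_field, coarse_grid):
        hardware = ~_tissue(coarse_grid)
        assert not coarse_field.porated[hardware].any()

    def test_whole_tumor_porated_at_4kv(self, coarse_field, coarse_grid):
        tumor = coarse_grid.material == LAB_TUMOR
        assert coarse_field.porated[tumor].all()

    def test_porated_set_monotone_in_voltage(self, default_scenario, coarse_grid):
        s = default_scenario
        prev = None
        for v in (1000.0, 2000.0, 3000.0, 4000.0):
            fs = porate_fixed_point(coarse_grid, s.materials, s.conductivity,
                                    v, 37.0, s.solver)
            if prev is not None:
                assert np.all(fs.porated | ~prev), \
                    "a voxel porated at lower voltage lost poration"
            prev = fs.porated


class TestFieldInvariants:
    def test_discrete_maximum_principle(self, coarse_field, default_scenario):
        v = default_scenario.protocol.voltage
        assert coarse_field.potential.min() >= -1e-9 * v
        assert coarse_field.potential.max() <= v * (1 + 1e-9)

    def test_charge_conservation_between_electrodes(self, coarse_field,
                                                    coarse_grid):
        ia = electrode_current(coarse_grid, coarse_field.potential,
                               coarse_field.sigma_effective, LAB_ELECTRODE_A)
        ib = electrode_current(coarse_grid, coarse_field.potential,
                               coarse_field.sigma_effective, LAB_ELECTRODE_B)
        assert ia == pytest.approx(-ib, rel=1e-6)
        assert ia > 0  # current flows out of the energized needle

    def test_joule_density_consistent_with_sigma_field(self, coarse_field):
        fs = coarse_field
        assert np.allclose(fs.joule_density,
                           fs.sigma_effective * fs.e_magnitude ** 2 *
                           (fs.e_magnitude > 0), rtol=1e-12, atol=1e-30)

    def test_temperature_coefficient_scales_sigma(self, default_scenario,
                                                  coarse_grid):
        """10 degC above reference raises every tissue sigma by 15%."""
        s = default_scenario
        hot = porate_fixed_point(coarse_grid, s.materials, s.conductivity,
                                 s.protocol.voltage, 47.0, s.solver)
        cold = porate_fixed_point(coarse_grid, s.materials, s.conductivity,
                                  s.protocol.voltage, 37.0, s.solver)
        t = _tissue(coarse_grid) & hot.porated & cold.porated
        assert np.allclose(hot.sigma_effective[t] / cold.sigma_effective[t],
                           1.15, rtol=1e-12)
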