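"""Analytic verification fixtures with packaged closed-form answers.

These are the stand-ins for an external finite-element oracle: scenarios
simple enough that every pipeline stage has an exact reference solution, yet
constructed so the *production* voxel solvers run on them (a slab is a grid
with planar electrode voxels, not a special-cased 1-D code path).

Fixtures: uniform and two-layer slabs (Laplace / Joule closed forms),
zero-dimensional uniform blocks (perfusion and metabolism ODEs), synthetic
sweeps with a known law coefficient (fit recovery) and constant-temperature
series (damage-integral closed form).  Every fixture carries its expected
answers in an ``expected`` dict.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np
import pandas as pd

from .damage import DamageParams, DEFAULT_DAMAGE
from .errors import FixtureError
from .meshing import (LAB_ELECTRODE_A, LAB_ELECTRODE_B, LAB_LIVER, LAB_TUMOR,
                      VoxelGrid)
from .scenario import (ConductivityModel, Geometry, LIVER, MaterialProperties,
                       PulseProtocol, Scenario, SolverSettings, TUMOR,
                       default_materials)
from .sweep_fit import COL_F, COL_PW, COL_TM, COL_V, SweepResult

__all__ = ["SlabFixture", "BlockFixture", "SeriesFixture", "make_slab",
           "make_two_layer_slab", "make_uniform_block", "make_synthetic_sweep",
           "make_constant_T_series"]


@dataclass
class SlabFixture:
    """Planar-electrode slab whose exact solution is a uniform field."""

    grid: VoxelGrid
    materials: Dict[str, MaterialProperties]
    conductivity_model: ConductivityModel
    voltage: float
    thickness: float
    expected: Dict[str, float]


def _slab_grid(thickness: float, n_cells: int, labels: np.ndarray) -> VoxelGrid:
    h = thickness / n_cells
    x_edges = np.linspace(-h, thickness + h, n_cells + 3)
    material = labels.reshape(-1, 1, 1)
    return VoxelGrid(x_edges, np.array([0.0, h]), np.array([0.0, h]), material)


def make_slab(thickness: float = 0.0054, material: MaterialProperties | None = None,
              voltage: float = 540.0, n_cells: int = 27,
              conductivity_model: ConductivityModel | None = None) -> SlabFixture:
    """Tissue slab between two plate electrodes.

    Exact solution: |E| = V/d, Q = sigma V^2/d^2 with sigma the porated or
    base conductivity depending on whether V/d reaches the threshold, and an
    adiabatic temperature rise Q/(rho c) per second of on-time (the uniform
    field has no gradients, so conduction is identically zero).
    """
    if thickness <= 0:
        raise FixtureError("make_slab: thickness must be > 0")
    mats = default_materials()
    props = material if material is not None else mats[TUMOR]
    mats[TUMOR] = props
    cm = conductivity_model or ConductivityModel()

    labels = np.full(n_cells + 2, LAB_TUMOR, dtype=np.int8)
    labels[0] = LAB_ELECTRODE_A
    labels[-1] = LAB_ELECTRODE_B
    grid = _slab_grid(thickness, n_cells, labels)

    e_mag = voltage / thickness
    porated = e_mag >= cm.e_threshold
    sigma = props.sigma_porated if porated else props.sigma_base
    q = sigma * e_mag**2
    expected = {
        "e_magnitude": e_mag,
        "porated": porated,
        "sigma": sigma,
        "q_density": q,
        "dT_per_on_second": q / props.volumetric_heat_capacity,
    }
    return SlabFixture(grid=grid, materials=mats, conductivity_model=cm,
                       voltage=voltage, thickness=thickness, expected=expected)


def make_two_layer_slab(thickness: float = 0.0054, sigma1: float = 0.067,
                        sigma2: float = 0.134, voltage: float = 1.0,
                        n_cells_per_layer: int = 10) -> SlabFixture:
    """Two equal tissue layers in series between plate electrodes.

    Current continuity fixes the per-layer fields:
    E_i = (V / sigma_i) / (d1/sigma1 + d2/sigma2); for equal thickness the
    field ratio is sigma2/sigma1.  The poration/temperature switches are
    disabled (threshold far above the applied field) so the closed form holds.
    """
    mats = default_materials()
    liver = mats[LIVER]
    tumor = mats[TUMOR]
    mats[LIVER] = MaterialProperties(rho=liver.rho, cp=liver.cp, k=liver.k,
                                     sigma_base=sigma1, sigma_porated=sigma1,
                                     omega_b=0.0, q_met=0.0)
    mats[TUMOR] = MaterialProperties(rho=tumor.rho, cp=tumor.cp, k=tumor.k,
                                     sigma_base=sigma2, sigma_porated=sigma2,
                                     omega_b=0.0, q_met=0.0)
    cm = ConductivityModel(e_threshold=1e12)

    labels = np.full(2 * n_cells_per_layer + 2, LAB_LIVER, dtype=np.int8)
    labels[0] = LAB_ELECTRODE_A
    labels[n_cells_per_layer + 1:] = LAB_TUMOR
    labels[-1] = LAB_ELECTRODE_B
    grid = _slab_grid(thickness, 2 * n_cells_per_layer, labels)

    d_half = thickness / 2.0
    resistance = d_half / sigma1 + d_half / sigma2
    e1 = voltage / sigma1 / resistance
    e2 = voltage / sigma2 / resistance
    expected = {"e_layer1": e1, "e_layer2": e2, "e_ratio": e1 / e2,
                "current_density": voltage / resistance}
    return SlabFixture(grid=grid, materials=mats, conductivity_model=cm,
                       voltage=voltage, thickness=thickness, expected=expected)


@dataclass
class BlockFixture:
    """Uniform zero-dimensional block with a closed-form T(t)."""

    scenario: Scenario
    grid: VoxelGrid
    closed_form: Callable[[float], float]
    expected: Dict[str, float]


def make_uniform_block(material_key: str = TUMOR, initial_t: float = 37.0,
                       conduction: bool = True, perfusion: bool = False,
                       metabolism: bool = False, joule: bool = False,
                       n: int = 3, size: float = 0.01) -> BlockFixture:
    """Uniform block with selected Pennes terms enabled.

    Closed forms (T uniform, conduction vanishes identically):
      metabolism only:  T(t) = T0 + Q_m t / (rho c)
      perfusion only:   T(t) = T_b + (T0 - T_b) exp(-rho_b c_b omega_b t/(rho c))
      both:             relaxation to T_b + Q_m/(rho_b c_b omega_b)
    Joule heating needs electrodes and is the slab fixture's job.
    """
    if joule:
        raise FixtureError("make_uniform_block: joule heating is exercised by "
                           "the slab fixture, not the block")
    if material_key not in (LIVER, TUMOR):
        raise FixtureError("make_uniform_block: material must be liver or tumor")

    mats = default_materials()
    base = mats[material_key]
    props = MaterialProperties(
        rho=base.rho, cp=base.cp, k=base.k, sigma_base=base.sigma_base,
        sigma_porated=base.sigma_porated,
        omega_b=base.omega_b if perfusion else 0.0,
        q_met=base.q_met if metabolism else 0.0)
    mats[material_key] = props
    if material_key == LIVER:
        # the reporting mask needs a tumor voxel; give it identical properties
        # so the block stays physically uniform
        mats[TUMOR] = props
    labels = np.full((n, n, n), LAB_TUMOR if material_key == TUMOR else LAB_LIVER,
                     dtype=np.int8)
    labels[n // 2, n // 2, n // 2] = LAB_TUMOR
    edges = np.linspace(0.0, size, n + 1)
    grid = VoxelGrid(edges, edges.copy(), edges.copy(), labels)

    scenario = Scenario(
        geometry=Geometry(), materials=mats,
        protocol=PulseProtocol(voltage=0.0, pulse_width=500.0, rep_rate=1000.0),
        initial_temperature=initial_t,
        solver=SolverSettings())

    blood = scenario.blood
    rc = props.volumetric_heat_capacity
    lam = blood.rho_b * blood.c_b * props.omega_b / rc
    heat_rate = props.q_met / rc

    def closed_form(t: float) -> float:
        if props.omega_b == 0.0:
            return initial_t + heat_rate * t
        t_inf = blood.t_b + props.q_met / (blood.rho_b * blood.c_b * props.omega_b)
        return t_inf + (initial_t - t_inf) * np.exp(-lam * t)

    expected = {"decay_rate": lam, "heating_rate": heat_rate,
                "t_at_1s": float(closed_form(1.0))}
    return BlockFixture(scenario=scenario, grid=grid, closed_form=closed_form,
                        expected=expected)


def make_synthetic_sweep(coefficient: float, voltages=None, widths=None,
                         rates=None, noise_sd: float = 0.0, seed: int = 0,
                         observable: str = COL_TM) -> SweepResult:
    """Sweep table generated from the exact scaling law
    observable = 37 + coefficient * p_w * f * V^2 (+ Gaussian noise).

    ``noise_sd = 0`` is exactly noiseless (no RNG draw), so fit recovery is
    machine-precision exact.
    """
    if noise_sd < 0:
        raise FixtureError("make_synthetic_sweep: noise_sd must be >= 0")
    from .sweep_fit import PAPER_RATES, PAPER_VOLTAGES, PAPER_WIDTHS
    voltages = PAPER_VOLTAGES if voltages is None else voltages
    widths = PAPER_WIDTHS if widths is None else widths
    rates = PAPER_RATES if rates is None else rates

    rows = [(float(v), float(pw), float(f))
            for v, pw, f in itertools.product(voltages, widths, rates)]
    table = pd.DataFrame(rows, columns=[COL_V, COL_PW, COL_F])
    x = table[COL_PW] * table[COL_F] * table[COL_V] ** 2
    values = 37.0 + coefficient * x
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=len(table))
    table[observable] = values
    return SweepResult(table=table)


@dataclass
class SeriesFixture:
    """Constant-temperature series with its closed-form damage integral."""

    times: np.ndarray
    temperatures: np.ndarray  # (n_times, 1)
    params: DamageParams
    expected_omega: float


def make_constant_T_series(temperature: float, duration: float, dt: float,
                           params: DamageParams = DEFAULT_DAMAGE) -> SeriesFixture:
    """Flat series at one temperature; Omega = A t exp(-E/(R T_K)) exactly."""
    if dt <= 0:
        raise FixtureError("make_constant_T_series: dt must be > 0")
    n = max(1, int(round(duration / dt)))
    times = np.linspace(0.0, duration, n + 1)
    temps = np.full((times.size, 1), float(temperature))
    omega = params.a_factor * duration * np.exp(
        -params.e_activation / (params.r_gas * (temperature + 273.15)))
    return SeriesFixture(times=times, temperatures=temps, params=params,
                         expected_omega=float(omega))
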