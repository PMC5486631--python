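"""Pennes bioheat integration through the pulse burst and cooling window.

The temperature field obeys

    rho c dT/dt = div(k grad T) + rho_b c_b omega_b (T_b - T) + Q_m + Q(t)

with harmonic face-averaged conductivity, a zero-flux outer boundary (the
liver surface is thermally insulated) and the Joule source Q gated by the
pulse train.  The burst phase uses cheap explicit forward-Euler steps (far
below the diffusion stability limit at these step sizes); the cooling phase
uses implicit backward Euler.  The electric field is re-solved whenever the
temperature has drifted enough to matter for the conductivity.

Temperatures are degrees Celsius throughout; the Kelvin conversion happens
only inside the Arrhenius kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import fv
from .damage import DamageAccumulator, DamageParams, DEFAULT_DAMAGE
from .electrostatics import FieldSolution, material_arrays, porate_fixed_point
from .errors import SolverError, ValidationError
from .meshing import (LAB_ELECTRODE_A, LAB_ELECTRODE_B, LAB_TUMOR, OUTSIDE,
                      TISSUE_LABELS, VoxelGrid, build_grid)
from .scenario import Scenario, pulse_schedule

__all__ = ["ThermalState", "BurstResult", "ThermalSystem", "pennes_rhs",
           "simulate_burst"]

# direct factorization only pays off for tiny systems; the backward-Euler
# matrix is strongly diagonally dominant (dt far below the diffusion time of
# any cell), so warm-started CG converges in a handful of iterations
_SPLU_MAX_CELLS = 5_000


@dataclass
class ThermalState:
    """Temperature snapshot at simulation time ``t`` (s)."""

    t: float
    temperature: np.ndarray  # degC, per voxel (NaN outside the domain)


@dataclass
class BurstResult:
    """Outcome of one simulated burst plus its observation window."""

    times: np.ndarray                    # s
    max_tumor_series: np.ndarray         # degC, per recorded time
    max_domain_series: np.ndarray        # degC
    t_burst_end: float                   # s
    peak_tumor_t_burst_end: float        # degC at the end of the burst
    peak_tumor_t_final: float            # degC at the end of the window
    peak_domain_t_burst_end: float
    peak_domain_t_final: float
    temperature_burst_end: np.ndarray    # degC field (NaN outside)
    temperature_final: np.ndarray
    omega: np.ndarray                    # damage field at the final time
    peak_tumor_omega: float
    t_final: float
    field_solution: Optional[FieldSolution]
    porated_voxels: int
    n_field_solves: int
    mode: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("BurstResult.times: must be strictly increasing")


class ThermalSystem:
    """Assembled discrete Pennes operator on a labeled grid.

    Solves over every voxel inside the liver cylinder (tissue plus electrode
    metal and sheath, each with its own rho, cp, k); perfusion and metabolism
    act on tissue only.  ``w`` is the per-cell heat capacity rho c V, and the
    balance reads  w dT/dt = -(K + P) T + P T_b + (Q_m + source) V.
    """

    def __init__(self, scenario: Scenario, grid: VoxelGrid):
        self.scenario = scenario
        self.grid = grid
        self.active = grid.material != OUTSIDE
        self.tissue3 = np.isin(grid.material, TISSUE_LABELS)
        self.tumor3 = grid.material == LAB_TUMOR
        if not self.tumor3.any():
            raise ValidationError("ThermalSystem: grid contains no tumor voxels")

        k3 = material_arrays(grid, scenario.materials, "k")
        rho3 = material_arrays(grid, scenario.materials, "rho")
        cp3 = material_arrays(grid, scenario.materials, "cp")
        omega_b3 = material_arrays(grid, scenario.materials, "omega_b")
        qmet3 = material_arrays(grid, scenario.materials, "q_met")

        K, _, self.index = fv.assemble_diffusion(grid, k3, self.active)
        vol = grid.volumes[self.active]
        self.w = (rho3 * cp3)[self.active] * vol               # J/K per cell
        blood = scenario.blood
        perf = (blood.rho_b * blood.c_b * omega_b3 * self.tissue3)[self.active] * vol
        sign = -1.0 if scenario.solver.pennes_printed_sign else 1.0
        # A T = conduction outflux + perfusion relaxation; c0 = constant sources
        self.A = (K + sp.diags(sign * perf)).tocsr()
        self.c0 = sign * perf * blood.t_b + qmet3[self.active] * vol
        self.tumor_rows = self.index[self.tumor3]
        self.tissue_rows = self.index[self.tissue3]
        self.n = int(self.active.sum())

    # -- helpers ----------------------------------------------------------
    def rhs(self, temperature: np.ndarray, source: np.ndarray | float = 0.0,
            ) -> np.ndarray:
        """dT/dt (degC/s) per active cell for a given volumetric source
        already integrated over cell volumes (W per cell)."""
        return (-(self.A @ temperature) + self.c0 + source) / self.w

    def explicit_dt_max(self) -> float:
        """Largest positivity-preserving forward-Euler step (s)."""
        diag = self.A.diagonal()
        positive = diag > 0
        if not positive.any():
            return math.inf
        return float(np.min(self.w[positive] / diag[positive]))

    def field_to_cells(self, arr3: np.ndarray) -> np.ndarray:
        return arr3[self.active]

    def cells_to_field(self, vec: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(self.grid.shape, fill)
        out[self.active] = vec
        return out

    def make_backward_euler(self, dt: float, rtol: float = 1e-10,
                            maxiter: int = 20000):
        """Return a solver f(T_old, extra_source) -> T_new for one BE step."""
        B = (sp.diags(self.w) + dt * self.A).tocsr()
        if self.n <= _SPLU_MAX_CELLS:
            lu = splu(B.tocsc())

            def step(t_old: np.ndarray, source=0.0) -> np.ndarray:
                return lu.solve(self.w * t_old + dt * (self.c0 + source))
        else:
            diag = B.diagonal()

            def step(t_old: np.ndarray, source=0.0) -> np.ndarray:
                rhs = self.w * t_old + dt * (self.c0 + source)
                sol, _ = fv.solve_spd(B, rhs, x0=t_old, rtol=rtol,
                                      maxiter=maxiter, name="bioheat implicit",
                                      diag=diag)
                return sol
        return step


def pennes_rhs(state: ThermalState, grid: VoxelGrid, scenario: Scenario,
               source: np.ndarray | float = 0.0) -> np.ndarray:
    """Per-voxel dT/dt (degC/s) of the Pennes equation for a given volumetric
    heat source (W/m^3); NaN outside the domain.  Convenience wrapper around
    :class:`ThermalSystem` for verification against closed forms."""
    system = ThermalSystem(scenario, grid)
    t_vec = system.field_to_cells(np.broadcast_to(
        np.asarray(state.temperature, float), grid.shape))
    src3 = np.broadcast_to(np.asarray(source, float), grid.shape)
    src = system.field_to_cells(src3 * system.tissue3 * grid.volumes)
    return system.cells_to_field(system.rhs(t_vec, src))


def _pulse_factor(scenario: Scenario, mode: str, t: float) -> float:
    if mode == "averaged":
        return scenario.protocol.duty_cycle
    return float(pulse_schedule(scenario.protocol, min(t, scenario.protocol.
                                                       burst_length_s * 0.999999)))


def simulate_burst(scenario: Scenario, grid: VoxelGrid | None = None,
                   mode: str = "exact", t_end: float | None = None,
                   damage_params: DamageParams = DEFAULT_DAMAGE) -> BurstResult:
    """Simulate one pulse burst and its observation window.

    mode="exact" gates the Joule source by the pulse train at the explicit
    step resolution; mode="averaged" applies the duty-cycle-scaled source
    continuously (equal deposited energy, peak differing by at most one
    single-pulse increment).  ``t_end`` defaults to the scenario's observation
    window (1 s); pass the burst length to stop at the end of the burst.
    """
    if mode not in ("exact", "averaged"):
        raise ValidationError(f"simulate_burst: unknown mode '{mode}'")
    settings = scenario.solver
    if grid is None:
        grid = build_grid(scenario.geometry, settings.resolution)
    system = ThermalSystem(scenario, grid)
    protocol = scenario.protocol
    t_end = settings.t_final if t_end is None else float(t_end)
    burst_len = protocol.burst_length_s
    if t_end < burst_len:
        raise ValidationError("simulate_burst: t_end must cover the burst")

    temperature = np.full(system.n, float(scenario.initial_temperature))
    vol = grid.volumes

    # --- electric field at burst start ------------------------------------
    has_electrodes = (np.any(grid.material == LAB_ELECTRODE_A)
                      and np.any(grid.material == LAB_ELECTRODE_B))
    fsol: Optional[FieldSolution] = None
    q_cells = 0.0
    n_solves = 0
    if protocol.voltage > 0.0 and has_electrodes:
        fsol = porate_fixed_point(grid, scenario.materials, scenario.conductivity,
                                  protocol.voltage,
                                  system.cells_to_field(temperature, fill=scenario.blood.t_b),
                                  settings)
        q_cells = system.field_to_cells(fsol.joule_density * vol)
        n_solves = 1

    # --- burst phase: explicit stepping ------------------------------------
    dt1 = settings.dt_burst if mode == "exact" else settings.dt_burst_averaged
    dt_max = system.explicit_dt_max()
    if dt1 >= dt_max:
        raise SolverError(
            f"simulate_burst: explicit step {dt1:g} s exceeds the stability "
            f"limit {dt_max:g} s; refine the step or coarsen the grid")
    n_steps = max(1, int(round(burst_len / dt1)))
    dt1 = burst_len / n_steps

    times = [0.0]
    max_tumor = [float(np.max(temperature[system.tumor_rows]))]
    max_domain = [float(np.max(temperature))]
    acc = DamageAccumulator(damage_params)
    acc.update(0.0, temperature[system.tissue_rows])

    t_ref_solve = temperature.copy()
    check_every = max(1, n_steps // 200)
    t = 0.0
    for i in range(n_steps):
        s = _pulse_factor(scenario, mode, t)
        temperature = temperature + dt1 * system.rhs(temperature, s * q_cells)
        t = (i + 1) * dt1
        if np.any(temperature < min(scenario.initial_temperature,
                                    scenario.blood.t_b) - 5.0):
            raise SolverError("simulate_burst: temperature blow-up during the burst")
        acc.update(t, temperature[system.tissue_rows])
        times.append(t)
        max_tumor.append(float(np.max(temperature[system.tumor_rows])))
        max_domain.append(float(np.max(temperature)))
        if (fsol is not None and (i + 1) % check_every == 0
                and float(np.max(np.abs(temperature - t_ref_solve))) > settings.refresh_dt):
            fsol = porate_fixed_point(grid, scenario.materials,
                                      scenario.conductivity, protocol.voltage,
                                      system.cells_to_field(temperature,
                                                            fill=scenario.blood.t_b),
                                      settings, porated0=fsol.porated,
                                      phi0=fsol.potential)
            q_cells = system.field_to_cells(fsol.joule_density * vol)
            t_ref_solve = temperature.copy()
            n_solves += 1

    peak_tumor_burst = max_tumor[-1]
    peak_domain_burst = max_domain[-1]
    field_burst_end = system.cells_to_field(temperature)

    # --- cooling phase: implicit stepping, source off -----------------------
    if t_end > burst_len + 1e-12:
        dt2 = settings.dt_cool
        n2 = max(1, int(math.ceil((t_end - burst_len) / dt2)))
        dt2 = (t_end - burst_len) / n2
        be_step = system.make_backward_euler(dt2, rtol=min(settings.cg_rtol, 1e-9),
                                             maxiter=settings.cg_maxiter)
        for j in range(n2):
            temperature = be_step(temperature)
            t = burst_len + (j + 1) * dt2
            acc.update(t, temperature[system.tissue_rows])
            times.append(t)
            max_tumor.append(float(np.max(temperature[system.tumor_rows])))
            max_domain.append(float(np.max(temperature)))

    omega3 = np.zeros(grid.shape)
    omega3[system.tissue3] = acc.field()
    tumor_omega = float(np.max(omega3[system.tumor3]))

    return BurstResult(
        times=np.asarray(times), max_tumor_series=np.asarray(max_tumor),
        max_domain_series=np.asarray(max_domain),
        t_burst_end=burst_len,
        peak_tumor_t_burst_end=peak_tumor_burst,
        peak_tumor_t_final=max_tumor[-1],
        peak_domain_t_burst_end=peak_domain_burst,
        peak_domain_t_final=max_domain[-1],
        temperature_burst_end=field_burst_end,
        temperature_final=system.cells_to_field(temperature),
        omega=omega3, peak_tumor_omega=tumor_omega,
        t_final=times[-1], field_solution=fsol,
        porated_voxels=int(fsol.porated.sum()) if fsol is not None else 0,
        n_field_solves=n_solves, mode=mode)
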