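"""Multi-parameter sweep, closed-form temperature-law fit and 44 degC envelope.

The peak tumor temperature responds linearly to pulse width and repetition
rate and quadratically to voltage, so the end-of-burst and end-of-window
maxima are summarized by the one-coefficient law

    T = T0 + a * p_w * f * V^2 * N        (p_w in ns, f in kHz, V in volts)

with the intercept fixed at the initial temperature T0 = 37 degC and N the
number of bursts (a linear upper-bound extrapolation valid while N is small).
Safe-parameter boundaries (the 44 degC envelope) are read off the simulated
response by interpolation that is exact under that scaling law: linear in
p_w and f, linear in V^2 for voltage.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FitError, SolverError, ValidationError
from .scenario import PulseProtocol, Scenario

logger = logging.getLogger(__name__)

__all__ = ["COL_V", "COL_PW", "COL_F", "COL_TM", "COL_TF", "COL_OMEGA",
           "PAPER_VOLTAGES", "PAPER_WIDTHS", "PAPER_RATES",
           "SweepResult", "FitResult", "run_sweep", "fit_power_law",
           "predict_temperature", "find_threshold_contour", "surface_44"]

COL_V = "voltage_v"
COL_PW = "pulse_width_ns"
COL_F = "rep_rate_khz"
COL_TM = "t_max_100us_c"
COL_TF = "t_max_1s_c"
COL_OMEGA = "omega_max_1s"
SWEEP_COLUMNS = (COL_V, COL_PW, COL_F, COL_TM, COL_TF, COL_OMEGA)

# the study's 4 x 4 x 4 lattice
PAPER_VOLTAGES = (1000.0, 2000.0, 3000.0, 4000.0)
PAPER_WIDTHS = (50.0, 100.0, 250.0, 500.0)
PAPER_RATES = (100.0, 250.0, 500.0, 1000.0)

T0_DEFAULT = 37.0


@dataclass
class SweepResult:
    """Peak temperatures and damage over a (V, p_w, f) lattice."""

    table: pd.DataFrame
    failed: List[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in (COL_V, COL_PW, COL_F) if c not in self.table.columns]
        if missing:
            raise ValidationError(f"SweepResult: missing columns {missing}")
        if self.table.duplicated([COL_V, COL_PW, COL_F]).any():
            raise ValidationError("SweepResult: duplicate lattice points")


@dataclass(frozen=True)
class FitResult:
    """Least-squares coefficient of the fixed-intercept temperature law."""

    coefficient: float       # degC per (ns * kHz * V^2)
    observable: str          # which column was fitted
    r_squared: float
    t0: float = T0_DEFAULT


def _as_table(sweep) -> pd.DataFrame:
    return sweep.table if isinstance(sweep, SweepResult) else pd.DataFrame(sweep)


def _point_key(scenario: Scenario, protocol: PulseProtocol, mode: str,
               t_end: float, n_cells: int) -> str:
    from .scenario import dump_scenario
    import dataclasses
    payload = {
        "scenario": dump_scenario(Scenario(
            geometry=scenario.geometry, materials=scenario.materials,
            blood=scenario.blood, protocol=protocol,
            conductivity=scenario.conductivity,
            initial_temperature=scenario.initial_temperature,
            solver=scenario.solver)),
        "mode": mode, "t_end": t_end, "n_cells": n_cells,
    }
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_sweep(scenario_template: Scenario, voltages: Sequence[float],
              widths: Sequence[float], rates: Sequence[float],
              mode: str = "averaged", grid=None, t_end: float | None = None,
              cache_dir: str | Path | None = None,
              damage_params=None) -> SweepResult:
    """Run one burst simulation per lattice point and tabulate the maxima.

    The grid is built once and shared (it does not depend on the protocol).
    Solver failures at individual points are recorded in ``SweepResult.failed``
    and the sweep continues.  With ``cache_dir`` set, finished points are
    stored as JSON keyed by a parameter hash and reused on re-runs.
    """
    from .bioheat import simulate_burst
    from .damage import DEFAULT_DAMAGE
    from .meshing import build_grid

    if not (len(voltages) and len(widths) and len(rates)):
        raise ValidationError("run_sweep: parameter lists must be non-empty")
    for pw, f in itertools.product(widths, rates):
        if pw * 1e-9 * f * 1e3 > 1.0 + 1e-12:
            raise ValidationError(
                f"run_sweep: pulse width {pw} ns at {f} kHz exceeds duty cycle 1")

    damage_params = damage_params or DEFAULT_DAMAGE
    if grid is None:
        grid = build_grid(scenario_template.geometry,
                          scenario_template.solver.resolution)
    t_end = scenario_template.solver.t_final if t_end is None else t_end
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    rows = []
    failed: List[dict] = []
    for volt, pw, f in itertools.product(voltages, widths, rates):
        protocol = PulseProtocol(voltage=float(volt), pulse_width=float(pw),
                                 rep_rate=float(f),
                                 burst_length=scenario_template.protocol.burst_length)
        entry = None
        if cache is not None:
            key = _point_key(scenario_template, protocol, mode, t_end, grid.n_cells)
            path = cache / f"{key}.json"
            if path.exists():
                entry = json.loads(path.read_text())
        if entry is None:
            point = Scenario(geometry=scenario_template.geometry,
                             materials=scenario_template.materials,
                             blood=scenario_template.blood, protocol=protocol,
                             conductivity=scenario_template.conductivity,
                             initial_temperature=scenario_template.initial_temperature,
                             solver=scenario_template.solver)
            try:
                res = simulate_burst(point, grid=grid, mode=mode, t_end=t_end,
                                     damage_params=damage_params)
            except SolverError as exc:
                logger.warning("sweep point (%.0f V, %.0f ns, %.0f kHz) failed: %s",
                               volt, pw, f, exc)
                failed.append({COL_V: volt, COL_PW: pw, COL_F: f, "error": str(exc)})
                continue
            entry = {COL_V: float(volt), COL_PW: float(pw), COL_F: float(f),
                     COL_TM: res.peak_tumor_t_burst_end,
                     COL_TF: res.peak_tumor_t_final,
                     COL_OMEGA: res.peak_tumor_omega}
            if cache is not None:
                path.write_text(json.dumps(entry))
        rows.append(entry)
    return SweepResult(table=pd.DataFrame(rows, columns=list(SWEEP_COLUMNS)),
                       failed=failed)


def fit_power_law(sweep, observable: str = COL_TM) -> FitResult:
    """Least-squares slope of (observable - T0) against x = p_w * f * V^2,
    through the origin (the intercept is pinned at T0 = 37 degC)."""
    table = _as_table(sweep)
    if observable not in table.columns:
        raise FitError(f"fit_power_law: no column '{observable}' in the sweep")
    data = table.dropna(subset=[observable])
    x = (data[COL_PW] * data[COL_F] * data[COL_V] ** 2).to_numpy(float)
    y = data[observable].to_numpy(float) - T0_DEFAULT
    if np.unique(x).size < 2:
        raise FitError("fit_power_law: degenerate design "
                       "(need >= 2 rows with distinct p_w * f * V^2)")
    a = float(x @ y / (x @ x))
    ss_res = float(np.sum((y - a * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return FitResult(coefficient=a, observable=observable, r_squared=r2)


def predict_temperature(fit, pulse_width: float, rep_rate: float, voltage: float,
                        n_bursts: int = 1) -> float:
    """Closed-form peak temperature T0 + a p_w f V^2 N (degC).

    ``fit`` is a :class:`FitResult` or a bare coefficient.  The linear-in-N
    extrapolation over bursts is an upper bound valid while N is not too
    large (inter-burst cooling is neglected).
    """
    if n_bursts < 1:
        raise ValidationError("predict_temperature: n_bursts must be >= 1")
    a = fit.coefficient if isinstance(fit, FitResult) else float(fit)
    t0 = fit.t0 if isinstance(fit, FitResult) else T0_DEFAULT
    return t0 + a * pulse_width * rep_rate * voltage**2 * n_bursts


def _axis_transform(axis: str):
    """Interpolation coordinate for an axis: V enters squared, others linear."""
    if axis == COL_V:
        return (lambda v: np.asarray(v, float) ** 2,
                lambda u: float(np.sqrt(u)))
    return (lambda v: np.asarray(v, float), float)


def find_threshold_contour(sweep, observable: str = COL_TM, limit: float = 44.0,
                           free: str = COL_F) -> pd.DataFrame:
    """Admissible-boundary points of the safe envelope.

    For every combination of the two pinned parameters present in the sweep,
    interpolates the response along the ``free`` axis (in V^2 when the free
    axis is voltage, since the response is quadratic in V and linear in p_w
    and f) to locate where the observable crosses ``limit``.  Points
    below/left of the boundary satisfy the limit.  Combinations whose
    response never reaches the limit are reported with status
    ``"unbounded within sweep range"`` rather than raising.
    """
    table = _as_table(sweep)
    if free not in (COL_V, COL_PW, COL_F):
        raise ValidationError(f"find_threshold_contour: unknown free axis '{free}'")
    others = [c for c in (COL_V, COL_PW, COL_F) if c != free]
    fwd, inv = _axis_transform(free)

    rows = []
    for pinned, group in table.groupby(others):
        group = group.dropna(subset=[observable]).sort_values(free)
        u = fwd(group[free].to_numpy())
        y = group[observable].to_numpy(float)
        entry = dict(zip(others, pinned))
        entry["free"] = free
        if len(group) < 2:
            entry.update(boundary=np.nan, status="insufficient data")
        elif np.all(y < limit):
            entry.update(boundary=np.nan, status="unbounded within sweep range")
        elif y[0] >= limit:
            entry.update(boundary=np.nan, status="exceeded at sweep minimum")
        else:
            idx = int(np.argmax(y >= limit))  # first point at/above the limit
            u_star = u[idx - 1] + (limit - y[idx - 1]) * (u[idx] - u[idx - 1]) \
                / (y[idx] - y[idx - 1])
            entry.update(boundary=inv(u_star), status="ok")
        rows.append(entry)
    return pd.DataFrame(rows)


def surface_44(sweep, observable: str = COL_TM, limit: float = 44.0,
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Triangulated isosurface of the response at ``limit`` in (V, p_w, f).

    The repetition rate is the elevation: for each (V, p_w) lattice column
    the crossing frequency is interpolated as in
    :func:`find_threshold_contour`; adjacent columns with crossings are
    stitched into triangles.  Returns (vertices, faces); the region toward
    the origin satisfies the limit.
    """
    contour = find_threshold_contour(sweep, observable, limit, free=COL_F)
    ok = contour[contour["status"] == "ok"]
    vertices = pd.DataFrame({
        COL_V: ok[COL_V].to_numpy(), COL_PW: ok[COL_PW].to_numpy(),
        COL_F: ok["boundary"].to_numpy()}).reset_index(drop=True)

    vert_id: Dict[tuple, int] = {
        (v, pw): i for i, (v, pw) in enumerate(zip(vertices[COL_V], vertices[COL_PW]))}
    volts = np.sort(vertices[COL_V].unique())
    widths = np.sort(vertices[COL_PW].unique())
    faces: List[tuple] = []
    for i in range(len(volts) - 1):
        for j in range(len(widths) - 1):
            quad = [(volts[i], widths[j]), (volts[i + 1], widths[j]),
                    (volts[i + 1], widths[j + 1]), (volts[i], widths[j + 1])]
            if all(q in vert_id for q in quad):
                a, b, c, d = (vert_id[q] for q in quad)
                faces.append((a, b, c))
                faces.append((a, c, d))
    return vertices, np.asarray(faces, dtype=int).reshape(-1, 3)
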