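"""Problem definition for pulse-burst tumor-ablation simulations.

A :class:`Scenario` bundles everything a run needs: the liver/tumor/needle
geometry, per-material electro-thermal properties, the arterial blood model,
the pulse-burst protocol, the stepped electroporation conductivity model and
the numerical solver settings.  Internally all lengths, times and energies are
SI; the pulse protocol keeps its field-conventional units (V, ns, kHz) because
the closed-form temperature law is written in them, and conversions happen at
module boundaries.

Scenarios round-trip through a YAML key-value document (:func:`load_scenario`
/ :func:`dump_scenario`); unknown keys are rejected so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import yaml

from .errors import ConfigError, ValidationError

__all__ = [
    "LIVER", "TUMOR", "ELECTRODE", "INSULATION", "REQUIRED_MATERIALS",
    "MaterialProperties", "BloodModel", "Geometry", "PulseProtocol",
    "ConductivityModel", "GridSpec", "SolverSettings", "Scenario",
    "default_materials", "default_scenario", "load_scenario", "dump_scenario",
    "duty_cycle", "total_on_time", "pulse_schedule",
]

# Material labels used as keys of Scenario.materials.
LIVER = "liver"
TUMOR = "tumor"
ELECTRODE = "electrode"
INSULATION = "insulation"
REQUIRED_MATERIALS = (LIVER, TUMOR, ELECTRODE, INSULATION)


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{name}: {msg}")


@dataclass(frozen=True)
class MaterialProperties:
    """Electro-thermal properties of one tissue or hardware material.

    Parameters
    ----------
    rho : mass density (kg/m^3)
    cp : specific heat capacity (J kg^-1 K^-1)
    k : thermal conductivity (W m^-1 K^-1)
    sigma_base : electrical conductivity before electroporation (S/m)
    sigma_porated : electrical conductivity after electroporation (S/m)
    omega_b : blood perfusion rate (1/s); zero for hardware
    q_met : metabolic volumetric heat source (W/m^3); zero for hardware
    """

    rho: float
    cp: float
    k: float
    sigma_base: float
    sigma_porated: float
    omega_b: float = 0.0
    q_met: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _check(getattr(self, f.name) >= 0.0, f"material.{f.name}", "must be >= 0")
        _check(self.sigma_porated >= self.sigma_base, "material.sigma_porated",
               "must be >= sigma_base (electroporation only raises conductivity)")

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * cp (J m^-3 K^-1)."""
        return self.rho * self.cp


@dataclass(frozen=True)
class BloodModel:
    """Arterial blood entering the Pennes perfusion term."""

    rho_b: float = 1000.0   # kg/m^3
    c_b: float = 4200.0     # J kg^-1 K^-1
    t_b: float = 37.0       # degC

    def __post_init__(self) -> None:
        _check(self.rho_b > 0, "blood.rho_b", "must be > 0")
        _check(self.c_b > 0, "blood.c_b", "must be > 0")


@dataclass(frozen=True)
class Geometry:
    """Cylindrical liver with a centered spherical tumor and two parallel needles.

    The needles run parallel to the cylinder axis (z), symmetric about the
    tumor center, separated by ``electrode_spacing`` center to center.  The
    energized segment of length ``active_length`` is centered on the tumor's
    equatorial plane; above it the needle is an insulated sheath up to the
    liver surface.  All lengths in meters.
    """

    liver_diameter: float = 0.10
    liver_height: float = 0.10
    tumor_diameter: float = 0.01
    needle_diameter: float = 0.001
    electrode_spacing: float = 0.0054
    active_length: float = 0.006
    tumor_center: Tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.tumor_center is None:
            object.__setattr__(self, "tumor_center",
                               (0.0, 0.0, self.liver_height / 2.0))
        else:
            object.__setattr__(self, "tumor_center", tuple(float(v) for v in self.tumor_center))
        for name in ("liver_diameter", "liver_height", "tumor_diameter",
                     "needle_diameter", "electrode_spacing", "active_length"):
            _check(getattr(self, name) > 0, f"geometry.{name}", "must be > 0")
        _check(self.electrode_spacing > self.needle_diameter,
               "geometry.electrode_spacing", "must exceed the needle diameter")
        cx, cy, cz = self.tumor_center
        r_t = self.tumor_diameter / 2.0
        _check(math.hypot(cx, cy) + r_t <= self.liver_diameter / 2.0 + 1e-12,
               "geometry.tumor_center", "tumor sphere must fit inside the liver cylinder")
        _check(r_t <= cz <= self.liver_height - r_t,
               "geometry.tumor_center", "tumor sphere must fit inside the liver height")


@dataclass(frozen=True)
class PulseProtocol:
    """One burst of a high-frequency nanosecond pulse train.

    ``voltage`` in volts, ``pulse_width`` in ns, ``rep_rate`` in kHz,
    ``burst_length`` in µs.  Bursts repeat at ``burst_rate`` Hz; only a single
    burst is simulated and multi-burst behavior is extrapolated analytically.
    """

    voltage: float
    pulse_width: float
    rep_rate: float
    burst_length: float = 100.0
    burst_rate: float = 1.0
    n_bursts: int = 1

    def __post_init__(self) -> None:
        _check(self.voltage >= 0, "protocol.voltage", "must be >= 0")
        _check(self.pulse_width > 0, "protocol.pulse_width", "must be > 0")
        _check(self.rep_rate > 0, "protocol.rep_rate", "must be > 0")
        _check(self.burst_length > 0, "protocol.burst_length", "must be > 0")
        _check(self.burst_rate > 0, "protocol.burst_rate", "must be > 0")
        _check(self.n_bursts >= 1, "protocol.n_bursts", "must be >= 1")
        _check(self.duty_cycle <= 1.0 + 1e-12, "protocol.pulse_width",
               f"duty cycle {self.duty_cycle:.3g} exceeds 1 "
               "(pulse width times repetition period)")

    @property
    def duty_cycle(self) -> float:
        """Fraction of the burst during which the voltage is high."""
        return self.pulse_width * 1e-9 * self.rep_rate * 1e3

    @property
    def total_on_time(self) -> float:
        """Total high-level duration within one burst (µs)."""
        return self.duty_cycle * self.burst_length

    @property
    def burst_length_s(self) -> float:
        return self.burst_length * 1e-6


@dataclass(frozen=True)
class ConductivityModel:
    """Stepped electroporation conductivity with a linear temperature coefficient.

    Tissue whose field magnitude reaches ``e_threshold`` (V/m) switches,
    irreversibly within a burst, from its base to its porated conductivity.
    Both states carry the multiplier ``1 + alpha * (T - t_ref)``.
    """

    e_threshold: float = 8.0e4   # V/m  (800 V/cm)
    alpha: float = 0.015         # 1/degC
    t_ref: float = 37.0          # degC

    def __post_init__(self) -> None:
        _check(self.e_threshold > 0, "conductivity.e_threshold", "must be > 0")
        _check(self.alpha >= 0, "conductivity.alpha", "must be >= 0")


@dataclass(frozen=True)
class GridSpec:
    """Graded structured-grid resolution.

    ``h_fine`` applies in a band around the needles (needle radius plus
    ``fine_margin`` radially, the active segment plus ``z_margin`` axially),
    growing by at most ``growth`` per cell out to ``h_coarse`` in the far
    field.  The default fine spacing equals the needle radius — the coarsest
    spacing that resolves the electrodes, and the sampling scale at which the
    near-electrode temperature maximum is defined (the continuum field is
    singular at the conductor edges, so the reported maximum is meaningful
    only at a stated scale; see the methods note).
    """

    h_fine: float = 5.0e-4
    h_coarse: float = 2.5e-3
    growth: float = 1.5
    fine_margin: float = 0.0
    z_margin: float = 0.0

    def __post_init__(self) -> None:
        _check(0 < self.h_fine <= self.h_coarse, "resolution.h_fine",
               "must satisfy 0 < h_fine <= h_coarse")
        _check(1.0 < self.growth <= 2.0, "resolution.growth", "must lie in (1, 2]")
        _check(self.fine_margin >= 0, "resolution.fine_margin", "must be >= 0")
        _check(self.z_margin >= 0, "resolution.z_margin", "must be >= 0")

    @classmethod
    def default(cls) -> "GridSpec":
        return cls()

    @classmethod
    def sweep(cls) -> "GridSpec":
        """Same near-electrode sampling as the default, leaner far field;
        meant for many-point parameter sweeps."""
        return cls(h_fine=5.0e-4, h_coarse=4.0e-3, fine_margin=0.0, z_margin=0.0)

    @classmethod
    def coarse(cls) -> "GridSpec":
        """Very coarse far field for smoke tests."""
        return cls(h_fine=5.0e-4, h_coarse=8.0e-3, fine_margin=0.0, z_margin=0.0)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the coupled solve.

    dt_burst : explicit step (s) during the burst in exact (pulse-gated) mode
    dt_burst_averaged : explicit step (s) in duty-cycle-averaged mode
    dt_cool : implicit step (s) after the burst
    t_final : end of the observation window (s)
    refresh_dt : re-solve the electric field when max |T - T_at_last_solve|
        exceeds this many degC (conductivity drifts with temperature)
    pennes_printed_sign : flip the perfusion term to the (unphysical) sign the
        source equation prints, for sensitivity checks
    """

    resolution: GridSpec = field(default_factory=GridSpec)
    dt_burst: float = 1.0e-8
    dt_burst_averaged: float = 1.0e-6
    dt_cool: float = 1.0e-3
    t_final: float = 1.0
    cg_rtol: float = 1.0e-8
    cg_maxiter: int = 20000
    refresh_dt: float = 1.0
    porate_max_iter: int = 50
    pennes_printed_sign: bool = False

    def __post_init__(self) -> None:
        for name in ("dt_burst", "dt_burst_averaged", "dt_cool", "t_final",
                     "cg_rtol", "refresh_dt"):
            _check(getattr(self, name) > 0, f"solver.{name}", "must be > 0")
        _check(self.cg_maxiter > 0, "solver.cg_maxiter", "must be > 0")
        _check(self.porate_max_iter >= 1, "solver.porate_max_iter", "must be >= 1")


def default_materials() -> Dict[str, MaterialProperties]:
    """Per-material defaults: rat liver and tumor with the stepped
    electroporation conductivities, stainless-steel electrodes and an
    insulating sheath."""
    return {
        LIVER: MaterialProperties(rho=1080.0, cp=3540.0, k=0.52,
                                  sigma_base=0.067, sigma_porated=0.241,
                                  omega_b=0.0005, q_met=4200.0),
        TUMOR: MaterialProperties(rho=1220.0, cp=4180.0, k=0.6,
                                  sigma_base=0.135, sigma_porated=0.426,
                                  omega_b=0.002, q_met=42000.0),
        ELECTRODE: MaterialProperties(rho=7010.0, cp=450.0, k=18.0,
                                      sigma_base=1.0e8, sigma_porated=1.0e8),
        INSULATION: MaterialProperties(rho=6450.0, cp=840.0, k=0.026,
                                       sigma_base=1.0e-5, sigma_porated=1.0e-5),
    }


@dataclass
class Scenario:
    """A complete, validated problem description."""

    geometry: Geometry = field(default_factory=Geometry)
    materials: Dict[str, MaterialProperties] = field(default_factory=default_materials)
    blood: BloodModel = field(default_factory=BloodModel)
    protocol: PulseProtocol = field(default_factory=lambda: PulseProtocol(
        voltage=4000.0, pulse_width=500.0, rep_rate=1000.0))
    conductivity: ConductivityModel = field(default_factory=ConductivityModel)
    initial_temperature: float | None = None
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        if self.initial_temperature is None:
            # default: tissue starts in equilibrium with arterial blood
            self.initial_temperature = self.blood.t_b
        for label in REQUIRED_MATERIALS:
            _check(label in self.materials, "materials",
                   f"missing required material '{label}'")
        _check(self.initial_temperature > -273.15, "initial_temperature",
               "must be above absolute zero")


def default_scenario(voltage: float = 4000.0, pulse_width: float = 500.0,
                     rep_rate: float = 1000.0, **scenario_kwargs) -> Scenario:
    """The reference scenario at a given burst protocol (defaults: the
    highest-energy protocol, 4 kV / 500 ns / 1 MHz)."""
    return Scenario(protocol=PulseProtocol(voltage=voltage, pulse_width=pulse_width,
                                           rep_rate=rep_rate), **scenario_kwargs)


# ---------------------------------------------------------------------------
# Pulse-train arithmetic


def duty_cycle(protocol: PulseProtocol) -> float:
    """Fraction of burst time at high level: pulse_width x rep_rate."""
    return protocol.duty_cycle


def total_on_time(protocol: PulseProtocol) -> float:
    """Total high-level duration within one burst, in µs."""
    return protocol.total_on_time


def pulse_schedule(protocol: PulseProtocol, t):
    """Gate function of the pulse train: 1 at high level, 0 otherwise.

    ``t`` is seconds since burst start (scalar or array, >= 0).  The train is
    a rectangular wave of period 1/rep_rate that stops at burst_length.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("pulse_schedule: t must be >= 0")
    period = 1.0 / (protocol.rep_rate * 1e3)
    width = protocol.pulse_width * 1e-9
    on = (np.mod(t_arr, period) < width) & (t_arr < protocol.burst_length_s)
    if np.isscalar(t) or t_arr.ndim == 0:
        return int(on)
    return on.astype(int)


# ---------------------------------------------------------------------------
# Configuration documents

_MATERIAL_FIELDS = tuple(f.name for f in dataclasses.fields(MaterialProperties))


def _build(cls, defaults, data, path):
    """Rebuild a frozen dataclass from ``defaults`` with overrides in ``data``."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"section '{path}' must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in allowed:
            raise ConfigError(f"unknown key '{path}.{key}'")
        kwargs[key] = value
    try:
        return dataclasses.replace(defaults, **kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{path}': {exc}") from exc


def load_scenario(config_text: str) -> Scenario:
    """Parse a YAML scenario document, applying defaults for omitted fields.

    Raises :class:`ConfigError` for parse failures or unknown keys (naming the
    offending line/key) and :class:`ValidationError` when a value violates a
    domain invariant.
    """
    try:
        raw = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"config parse failure{where}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config document must be a mapping of sections")

    known = {"geometry", "materials", "blood", "protocol", "conductivity",
             "solver", "initial_temperature"}
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown key '{key}'")

    geometry = _build(Geometry, Geometry(), raw.get("geometry"), "geometry")
    materials = default_materials()
    mats_raw = raw.get("materials") or {}
    if not isinstance(mats_raw, dict):
        raise ConfigError("section 'materials' must be a mapping")
    for label, props in mats_raw.items():
        if label not in materials:
            raise ConfigError(f"unknown key 'materials.{label}'")
        materials[label] = _build(MaterialProperties, materials[label], props,
                                  f"materials.{label}")
    blood = _build(BloodModel, BloodModel(), raw.get("blood"), "blood")
    protocol = _build(PulseProtocol,
                      PulseProtocol(voltage=4000.0, pulse_width=500.0, rep_rate=1000.0),
                      raw.get("protocol"), "protocol")
    conductivity = _build(ConductivityModel, ConductivityModel(),
                          raw.get("conductivity"), "conductivity")

    solver_raw = dict(raw.get("solver") or {})
    if not isinstance(solver_raw, dict):
        raise ConfigError("section 'solver' must be a mapping")
    resolution = _build(GridSpec, GridSpec(), solver_raw.pop("resolution", None),
                        "solver.resolution")
    solver = _build(SolverSettings, SolverSettings(resolution=resolution),
                    solver_raw, "solver")

    return Scenario(geometry=geometry, materials=materials, blood=blood,
                    protocol=protocol, conductivity=conductivity,
                    initial_temperature=raw.get("initial_temperature"),
                    solver=solver)


def dump_scenario(scenario: Scenario) -> str:
    """Serialize a scenario to the same YAML document format
    :func:`load_scenario` accepts (round-trips to an equal Scenario)."""
    doc = {
        "geometry": {**dataclasses.asdict(scenario.geometry),
                     "tumor_center": list(scenario.geometry.tumor_center)},
        "materials": {label: dataclasses.asdict(props)
                      for label, props in scenario.materials.items()},
        "blood": dataclasses.asdict(scenario.blood),
        "protocol": dataclasses.asdict(scenario.protocol),
        "conductivity": dataclasses.asdict(scenario.conductivity),
        "initial_temperature": scenario.initial_temperature,
        "solver": dataclasses.asdict(scenario.solver),
    }
    return yaml.safe_dump(doc, sort_keys=True)
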