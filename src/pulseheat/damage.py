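"""Arrhenius thermal-damage integral, kill probability and classification.

The cumulative damage Omega(t) = integral of A exp(-E / (R T(t))) dt with T in
kelvin; the default kinetics are protein coagulation (A = 7.39e39 1/s,
E = 2.577e5 J/mol), with microvascular blood-flow stasis and whole-cell death
available as named presets.  Kill probability maps Omega through
P(%) = 100 (1 - exp(-Omega)); Omega = 1 corresponds to 63% and Omega = 4.6 to
99%, and Omega = 0.53 is used as the onset-of-damage threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["R_GAS", "DamageParams", "DAMAGE_PRESETS", "DamageField",
           "arrhenius_rate", "DamageAccumulator", "integrate_damage",
           "kill_probability", "classify_damage",
           "OMEGA_DAMAGE_THRESHOLD", "OMEGA_P63", "OMEGA_P99"]

R_GAS = 8.314  # J mol^-1 K^-1

OMEGA_DAMAGE_THRESHOLD = 0.53
OMEGA_P63 = 1.0
OMEGA_P99 = 4.6


@dataclass(frozen=True)
class DamageParams:
    """First-order Arrhenius kinetics: pre-exponential factor A (1/s) and
    activation energy E (J/mol)."""

    a_factor: float
    e_activation: float
    r_gas: float = R_GAS

    def __post_init__(self) -> None:
        if self.a_factor <= 0:
            raise ValidationError("damage.a_factor: must be > 0")
        if self.e_activation <= 0:
            raise ValidationError("damage.e_activation: must be > 0")


DAMAGE_PRESETS = {
    "protein_coagulation": DamageParams(a_factor=7.39e39, e_activation=2.577e5),
    "microvascular_stasis": DamageParams(a_factor=1.98e106, e_activation=6.67e5),
    "cell_death": DamageParams(a_factor=2.984e80, e_activation=5.064e5),
}
DEFAULT_DAMAGE = DAMAGE_PRESETS["protein_coagulation"]


@dataclass
class DamageField:
    """Accumulated damage Omega per voxel up to time ``t``."""

    omega: np.ndarray
    t: float


def arrhenius_rate(temperature, params: DamageParams = DEFAULT_DAMAGE):
    """Instantaneous damage rate A exp(-E/(R T_K)) in 1/s; temperature in degC."""
    t_kelvin = np.asarray(temperature, float) + 273.15
    if np.any(t_kelvin <= 0):
        raise ValidationError("arrhenius_rate: temperature at or below absolute zero")
    return params.a_factor * np.exp(-params.e_activation / (params.r_gas * t_kelvin))


class DamageAccumulator:
    """Streaming trapezoidal accumulation of the damage integral.

    Feed strictly increasing times with per-voxel temperatures; the result
    equals batch integration of the same samples to round-off.
    """

    def __init__(self, params: DamageParams = DEFAULT_DAMAGE):
        self.params = params
        self._last_t: float | None = None
        self._last_rate: np.ndarray | None = None
        self.omega: np.ndarray | float = 0.0

    def update(self, t: float, temperature) -> None:
        rate = np.asarray(arrhenius_rate(temperature, self.params), float)
        if self._last_t is not None:
            if t < self._last_t:
                raise ValidationError("DamageAccumulator: times must be non-decreasing")
            self.omega = self.omega + 0.5 * (t - self._last_t) * (rate + self._last_rate)
        self._last_t = t
        self._last_rate = rate

    def field(self, shape=None) -> np.ndarray:
        omega = np.asarray(self.omega, float)
        if shape is not None and omega.shape != tuple(shape):
            omega = np.broadcast_to(omega, shape).copy()
        return omega


def integrate_damage(times, temperatures, params: DamageParams = DEFAULT_DAMAGE,
                     ) -> DamageField:
    """Batch trapezoidal damage integral over a temperature series.

    ``times``: strictly increasing 1-D array (s); ``temperatures``: array whose
    leading axis matches ``times`` (remaining axes are voxels).
    """
    times = np.asarray(times, float)
    temps = np.asarray(temperatures, float)
    if times.ndim != 1 or temps.shape[0] != times.size:
        raise ValidationError("integrate_damage: leading axis of temperatures "
                              "must match times")
    if times.size and np.any(np.diff(times) < 0):
        raise ValidationError("integrate_damage: times must be non-decreasing")
    if times.size < 2:
        shape = temps.shape[1:] if temps.ndim > 1 else ()
        return DamageField(np.zeros(shape), float(times[-1]) if times.size else 0.0)
    rates = arrhenius_rate(temps, params)
    omega = np.trapezoid(rates, times, axis=0)
    return DamageField(np.asarray(omega, float), float(times[-1]))


def kill_probability(omega):
    """Cell-kill probability in percent: 100 (1 - exp(-Omega))."""
    omega_arr = np.asarray(omega, float)
    if np.any(omega_arr < 0):
        raise ValidationError("kill_probability: omega must be >= 0")
    p = 100.0 * (1.0 - np.exp(-omega_arr))
    return float(p) if np.isscalar(omega) or omega_arr.ndim == 0 else p


def classify_damage(omega):
    """Threshold classification of Omega.

    below_threshold (< 0.53), damaged (>= 0.53), p63 (>= 1) and p99 (>= 4.6);
    boundaries are inclusive upward.
    """
    omega_arr = np.asarray(omega, float)
    if np.any(omega_arr < 0):
        raise ValidationError("classify_damage: omega must be >= 0")
    labels = np.select(
        [omega_arr >= OMEGA_P99, omega_arr >= OMEGA_P63,
         omega_arr >= OMEGA_DAMAGE_THRESHOLD],
        ["p99", "p63", "damaged"], default="below_threshold")
    if np.isscalar(omega) or omega_arr.ndim == 0:
        return str(labels)
    return labels
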