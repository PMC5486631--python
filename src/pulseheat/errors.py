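"""Exception hierarchy for the pulseheat package."""


class PulseHeatError(Exception):
    """Base class for all pulseheat errors."""


class ConfigError(PulseHeatError):
    """A scenario configuration document failed to parse or contained unknown keys."""


class ValidationError(PulseHeatError, ValueError):
    """A domain object violated one of its invariants; the message names the field."""


class MeshError(PulseHeatError):
    """A grid resolution request cannot represent the geometry."""


class SolverError(PulseHeatError, RuntimeError):
    """A linear solve or fixed-point iteration failed to converge."""


class FitError(PulseHeatError):
    """The sweep table cannot support the requested fit (degenerate design)."""


class FixtureError(PulseHeatError):
    """An analytic verification fixture was requested with unsupported options."""
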