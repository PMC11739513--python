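"""Exception hierarchy.

Every failure mode surfaces as a subclass of :class:`HepavascError` so CLI
commands can name the failing stage without catching bare exceptions.
"""


class HepavascError(Exception):
    """Base class for all package errors."""


class GeometryError(HepavascError):
    """Invalid or degenerate organ geometry (non-watertight mesh, point
    outside the volume, zero enclosed volume)."""


class ArgumentError(HepavascError, ValueError):
    """Invalid argument value (non-positive radius, k > number of points)."""


class InfeasibilityError(HepavascError):
    """A physical budget or boundary condition cannot be met (vessel volume
    exceeds blood volume; no non-negative R_SL admits the target flow)."""


class GrowthError(HepavascError):
    """Space colonization failed to reach all target attractors."""

    def __init__(self, message, unreached=()):
        super().__init__(message)
        self.unreached = tuple(unreached)


class TopologyError(HepavascError):
    """Inconsistent network topology (mismatched terminal sets, a branch
    child serving zero super lobules, disconnected graph)."""


class SolverError(HepavascError):
    """The linear pressure/flow system is singular or failed to solve."""


class SimulationError(HepavascError):
    """Perfusion simulation cannot proceed (cyclic element graph)."""


class TimeStepError(SimulationError):
    """Explicit time step too large for at least one element."""

    def __init__(self, message, max_stable_dt=None, element=None):
        super().__init__(message)
        self.max_stable_dt = max_stable_dt
        self.element = element


class ConfigError(HepavascError):
    """Invalid run configuration (unknown key, schema violation)."""
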