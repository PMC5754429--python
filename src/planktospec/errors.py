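"""Exception types shared across the package."""


class PlanktospecError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PlanktospecError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InfeasibleGrowthError(PlanktospecError):
    """Growth stalls somewhere in the size interval (uptake does not exceed
    metabolic loss), so the requested quantity is undefined."""


class ExtinctionOnlyError(PlanktospecError):
    """No coexistence root exists in the feasible nutrient bracket; the only
    steady state is full extinction."""


class KernelError(PlanktospecError, ValueError):
    """A kernel shape violates a structural requirement (normalisation,
    symmetry, divergence of the division-rate integral, finite moments)."""


class CFLError(PlanktospecError):
    """A requested time step violates the advection/sink stability bound."""


class BlowUpError(PlanktospecError):
    """A simulated density exceeded the overflow guard."""


class EstimationError(PlanktospecError):
    """A measurement (e.g. growth-rate fit) was refused on invalid input."""


class NoZooplanktonStateError(PlanktospecError):
    """The coupled phyto-zooplankton equations admit no steady state with a
    non-negative zooplankton spectrum coefficient for these parameters."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


class ConfigError(PlanktospecError, ValueError):
    """A configuration file violates an invariant; carries the field path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")
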