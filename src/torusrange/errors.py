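"""Exception hierarchy.

All package errors derive from :class:`TorusRangeError` so callers can catch
one base class; most also derive from a matching builtin (``ValueError`` /
``RuntimeError``) to behave well in generic code.
"""


class TorusRangeError(Exception):
    """Base class for all torusrange errors."""


class FormatError(TorusRangeError, ValueError):
    """An input table does not match the expected CSV layout."""


class GeometryError(TorusRangeError, ValueError):
    """A grid/plot geometry mismatch or an invalid geometry parameter."""


class DegenerateGeometryError(GeometryError):
    """Too few or collinear points to form a polygon."""


class ConvergenceError(TorusRangeError, RuntimeError):
    """An iterative criterion (e.g. LSCV) has no interior optimum."""


class SingularSystemError(TorusRangeError, ValueError):
    """A linear system (e.g. kriging) is singular, usually coincident points."""


class VariogramFitError(TorusRangeError, RuntimeError):
    """Variogram model fitting failed on all starts."""

    def __init__(self, message, empirical=None):
        super().__init__(message)
        self.empirical = empirical


class DegenerateGradientError(TorusRangeError, ValueError):
    """Habitat variable is constant; the association test is undefined."""


class SimulationError(TorusRangeError, RuntimeError):
    """The synthetic generator could not satisfy its constraints."""


class IndeterminateSignError(TorusRangeError, ValueError):
    """Association sign cannot be determined (exact tie)."""


class ConfigurationError(TorusRangeError, ValueError):
    """Invalid run configuration."""
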