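"""Exception hierarchy.

All errors derive from :class:`CimexolfError` so callers can catch the
package's failures with a single except clause; most are also ``ValueError``
subclasses because they signal bad inputs.
"""


class CimexolfError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CimexolfError, ValueError):
    """A numeric parameter is outside its valid domain."""


class SchemaError(CimexolfError, ValueError):
    """A table, trace or config does not match the expected schema."""


class OutOfRangeError(CimexolfError, ValueError):
    """A requested window falls outside the recording."""


class InsufficientBaselineError(CimexolfError, ValueError):
    """Stimulus onset leaves no full 500 ms pre-stimulus window."""


class InvalidBinningError(CimexolfError, ValueError):
    """PSTH window is not an integer multiple of the bin width."""


class DegenerateThresholdError(CimexolfError, ValueError):
    """Adaptive threshold undefined (flat trace); use an absolute threshold."""


class DegenerateColumnError(CimexolfError, ValueError):
    """A constant matrix column cannot be standardized."""


class UndefinedKurtosisError(CimexolfError, ValueError):
    """Kurtosis undefined for a constant vector."""


class InsufficientDataError(CimexolfError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedIndexError(CimexolfError, ValueError):
    """Phasic/tonic index undefined (zero peak rate)."""


class FitFailureError(CimexolfError, RuntimeError):
    """Nonlinear fit failed to converge from every starting point."""


class DependencyError(CimexolfError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
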