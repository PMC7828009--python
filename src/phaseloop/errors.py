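"""Exception types raised across the package.

All inherit from :class:`PhaseloopError` (a ``ValueError``), so callers can
catch package errors collectively or rely on standard ``ValueError`` handling.
"""


class PhaseloopError(ValueError):
    """Base class for all phaseloop errors."""


class ConfigError(PhaseloopError):
    """A configuration object violates its invariants."""


class LengthError(PhaseloopError):
    """An input series is too short (or empty) for the requested operation."""


class ParameterError(PhaseloopError):
    """A scalar parameter is out of its valid range."""


class ShapeError(PhaseloopError):
    """An array argument has the wrong shape."""


class DegenerateInputError(PhaseloopError):
    """The input carries no usable signal (e.g. zero variance)."""


class UndefinedMeanError(PhaseloopError):
    """The circular mean is undefined (zero resultant length)."""


class EmptyResultError(PhaseloopError):
    """No usable data remained to form the requested result."""
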