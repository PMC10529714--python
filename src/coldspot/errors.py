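"""Exception hierarchy for coldspot."""


class ColdspotError(Exception):
    """Base class for all package errors."""


class CompositionError(ColdspotError):
    """Invalid composition mass fractions."""


class ComponentPropertyError(ColdspotError):
    """Invalid per-component property values."""


class ParameterError(ColdspotError):
    """A scalar parameter is outside its admissible range."""


class ScheduleError(ColdspotError):
    """Inconsistent or invalid process schedule."""


class DomainError(ColdspotError):
    """A query point (time or space) lies outside the simulated domain."""


class SolverError(ColdspotError):
    """Failure inside the transient conduction solver."""


class EigenvalueError(ColdspotError):
    """Bracketed root search for a series eigenvalue failed."""


class AlignmentError(ColdspotError):
    """Two series cannot be aligned (length or timestamp mismatch)."""


class LoggerDataError(ColdspotError):
    """Malformed logger dataset."""


class IdentifiabilityError(ColdspotError):
    """The data window cannot constrain the requested parameters."""


class ConfigError(ColdspotError):
    """Configuration file failed validation."""
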