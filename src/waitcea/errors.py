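"""Exception hierarchy shared across the package."""


class WaitceaError(Exception):
    """Base class for all package errors."""


class ParseError(WaitceaError):
    """A file could not be parsed (malformed field, bad header)."""


class ValidationError(WaitceaError):
    """Parsed data violates a domain invariant."""


class ConfigurationError(WaitceaError):
    """A costing table or analysis configuration is incomplete or inconsistent."""


class EstimationError(WaitceaError):
    """An estimator's preconditions are not met (e.g. an empty arm-wave cell)."""


class SpecError(WaitceaError):
    """A simulation specification is internally inconsistent."""
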