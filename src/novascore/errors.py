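"""Exception hierarchy shared across the package.

Distinct classes map to distinct CLI exit codes: data/config validation
problems (2), usage errors (3), and runtime/identifiability failures (4).
"""

__all__ = [
    "NovaScoreError",
    "InstrumentError",
    "ValidationError",
    "UsageError",
    "IdentifiabilityError",
    "EmptyInputError",
]


class NovaScoreError(Exception):
    """Base class for all package errors."""


class InstrumentError(NovaScoreError):
    """Malformed or internally inconsistent instrument definition."""


class ValidationError(NovaScoreError):
    """Input data violates a contract (bad rating, unknown item, ...)."""


class UsageError(NovaScoreError):
    """Caller invoked an operation with an incompatible mode or config."""


class IdentifiabilityError(NovaScoreError):
    """A statistical quantity cannot be estimated from the given design."""


class EmptyInputError(ValidationError):
    """An operation received an empty table where rows were required."""
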