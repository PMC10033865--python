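"""Exception hierarchy shared across the package."""


class FarolcareError(Exception):
    """Base class for all package errors."""


class DomainError(FarolcareError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class DataValidationError(FarolcareError, ValueError):
    """Input data violates a structural contract (e.g. non-consecutive dates)."""


class ResourceError(FarolcareError, RuntimeError):
    """A computation was refused because it would be too large to enumerate."""
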