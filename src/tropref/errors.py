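"""Exception hierarchy shared by all tropref modules."""


class TroprefError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TroprefError):
    """Invalid generator or pipeline configuration; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DomainError(TroprefError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class ValidationError(TroprefError, ValueError):
    """Malformed input data (missing fields, non-finite values, ...)."""
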