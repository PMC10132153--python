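"""Exception hierarchy shared across the package."""


class TransregError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TransregError, ValueError):
    """An invalid configuration field; the message names the field."""


class ValidationError(TransregError, ValueError):
    """Malformed or inconsistent input data."""


class SchemaError(ValidationError):
    """Tables whose sample metadata or layout violates the expected schema."""


class InsufficientReplicatesError(ValidationError):
    """Fewer than two usable replicate values for a statistical test."""


class UndefinedRatioError(ValidationError):
    """A fold-change or PM ratio whose denominator is zero."""
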