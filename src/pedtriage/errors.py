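"""Exception types shared across the pipeline."""


class PedtriageError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PedtriageError, ValueError):
    """Invalid configuration; the message names the offending field."""


class SchemaError(PedtriageError, ValueError):
    """Cohort file does not match the expected schema."""


class DataError(PedtriageError, ValueError):
    """Inconsistent or unusable values inside an otherwise valid table."""


class DomainError(PedtriageError, ValueError):
    """Input outside the physiological or mathematical domain of an operation."""
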