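"""Exception hierarchy shared across the pipeline stages."""


class SafetyomeError(Exception):
    """Base class for all package errors."""


class SchemaError(SafetyomeError):
    """An input table is missing a required column or has malformed values."""


class ConfigurationError(SafetyomeError):
    """A run/stage configuration is inconsistent or incomplete."""


class ValidationError(SafetyomeError):
    """A value violates a documented precondition (bad threshold, negative count...)."""
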