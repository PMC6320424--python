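"""Exception hierarchy shared across the pipeline stages."""


class EmrForgeError(Exception):
    """Base class for all package errors."""


class InvalidCodeError(EmrForgeError):
    """A diagnosis code is empty or cannot be normalized."""


class SchemaError(EmrForgeError):
    """An input table is missing required columns or violates key constraints."""


class IntegrityError(EmrForgeError):
    """Cross-table referential integrity is broken (e.g. visit without patient)."""


class ConfigError(EmrForgeError):
    """A configuration value is missing, inconsistent, or out of range."""


class UndefinedRateError(EmrForgeError):
    """A rate was requested with a zero denominator."""


class AnalysisError(EmrForgeError):
    """A statistical routine received degenerate input (constant vector,
    single group, empty margin)."""
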