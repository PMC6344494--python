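"""Exception types shared across the package."""


class FloradivError(Exception):
    """Base class for package errors."""


class SchemaError(FloradivError):
    """Input table lacks a required column or maps one ambiguously."""


class ValidationError(FloradivError):
    """Input rows violate a record invariant (bad stage label, duplicate id)."""


class ConfigError(FloradivError):
    """A configuration value is out of range or internally inconsistent."""


class UndefinedResultError(FloradivError):
    """A well-formed request whose answer is mathematically undefined
    (e.g. an extinction fraction over zero standing diversity, or scaling
    a constant series)."""
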