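"""Exception hierarchy shared across the pipeline stages."""


class FlorastatError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FlorastatError):
    """A configuration value is missing, mistyped or out of range."""


class ValidationError(FlorastatError):
    """Input data violate a schema, vocabulary or precondition."""


class SchemaError(FlorastatError):
    """A required column or file-level structure is absent."""


class ConvergenceError(FlorastatError):
    """A model fit failed to converge and no usable result exists."""
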