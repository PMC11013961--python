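"""Exception hierarchy shared across the package."""


class TasselCountError(Exception):
    """Base class for all package errors."""


class FormatError(TasselCountError):
    """An input file decodes but has the wrong structure (e.g. grayscale image)."""


class SchemaError(TasselCountError):
    """A tabular input is missing required columns."""


class ValidationError(TasselCountError):
    """An input value violates a documented precondition."""


class ConfigurationError(TasselCountError):
    """A configuration value is unknown or inconsistent (e.g. unregistered index name)."""


class UndefinedCorrelationError(TasselCountError):
    """A correlation statistic is requested on zero-variance data."""
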