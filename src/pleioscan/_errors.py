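"""Exception hierarchy shared across the package."""


class PleioscanError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PleioscanError):
    """A configuration value is invalid; message names the offending field."""


class DataError(PleioscanError):
    """Input data violate a precondition (empty, non-finite, degenerate)."""


class SchemaError(PleioscanError):
    """A table is missing required columns or has an incompatible layout."""


class FitInfeasibleError(PleioscanError):
    """Too few rows (or a rank-deficient design) to fit the requested model."""
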