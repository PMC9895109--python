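"""Exception hierarchy shared across the package."""


class PgagpError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PgagpError):
    """A line of an input file could not be parsed."""


class ValidationError(PgagpError):
    """Input data violates a structural invariant."""


class ConfigError(PgagpError):
    """A configuration value is outside its admissible range."""


class DegenerateSpectrumError(PgagpError):
    """The feature Gram matrix has no positive eigenvalue, so no
    dimension can be selected."""
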