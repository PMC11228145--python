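"""Exception hierarchy shared across the package."""


class GlucotabError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GlucotabError):
    """Table structure does not match the declared schema."""


class ParseError(GlucotabError):
    """A cell could not be parsed as the declared attribute kind."""


class ParameterError(GlucotabError, ValueError):
    """An operation received an out-of-range parameter."""


class DataError(GlucotabError):
    """Input data violate an operation's precondition."""


class TrainingError(GlucotabError):
    """Optimisation failed (e.g. divergent loss)."""
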