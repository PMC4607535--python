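"""Exception hierarchy shared across the pipeline stages."""


class RatescopeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RatescopeError):
    """Invalid parameter values, distribution families, or config files."""


class DataError(RatescopeError):
    """Input data violate a documented precondition."""


class IntegrationError(RatescopeError):
    """Numerical integration produced a non-finite state."""


class ParseError(DataError):
    """A delimited-text input does not conform to the documented schema."""
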