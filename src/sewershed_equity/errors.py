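"""Exception hierarchy.

``ConfigurationError`` and ``ValidationError`` map to CLI exit code 1,
I/O problems to exit code 2.
"""


class SewershedEquityError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SewershedEquityError):
    """Invalid configuration (bad parameter value, impossible gradient, ...)."""


class ValidationError(SewershedEquityError):
    """Input data violates the census data model (bad join, out-of-range value)."""


class GeometryError(SewershedEquityError):
    """Invalid or irreparable geometry, or an illegal geometric operation."""
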