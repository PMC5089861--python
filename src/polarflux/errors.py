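"""Exception hierarchy.

The CLI maps :class:`ConfigurationError` to exit code 2 and
:class:`DataError` to exit code 3; everything else is a bug.
"""


class PolarfluxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PolarfluxError, ValueError):
    """A parameter or configuration value is invalid; message names the field."""


class DataError(PolarfluxError, ValueError):
    """Input data violate the declared schema or preconditions."""


class DegenerateConversionError(DataError):
    """Photoconversion denominator below the guard threshold (conversion failed)."""
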