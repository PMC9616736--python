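"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses)
to exit code 3.
"""


class ThirstStateError(Exception):
    """Base class for all package errors."""


class ConfigError(ThirstStateError):
    """Invalid configuration: bad parameter ranges, unknown keys, bad schema."""


class DataError(ThirstStateError):
    """Invalid or inconsistent input data."""


class InsufficientDataError(DataError):
    """Too few observations to run the requested estimator."""
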