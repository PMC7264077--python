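"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes so callers can tell a bad
configuration from bad data or a numerical failure.
"""


class MegPLSError(Exception):
    """Base class for all package errors."""


class ConfigError(MegPLSError):
    """Invalid or inconsistent configuration (exit code 2)."""


class DataError(MegPLSError):
    """Invalid, missing or unusable data (exit code 3)."""


class NumericalError(MegPLSError):
    """Numerical failure such as a singular covariance (exit code 4)."""
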