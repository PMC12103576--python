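"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class CotrackError(Exception):
    """Base class for all package errors."""


class ConfigError(CotrackError):
    """Invalid parameters or configuration."""


class DataError(CotrackError):
    """Input data violates a precondition (empty, inconsistent, unusable)."""
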