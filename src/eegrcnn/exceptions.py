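"""Exception hierarchy shared across the package.

``DataError`` covers malformed or unreadable inputs (CLI exit code 2);
``ValidationError`` covers semantically invalid values (inverted intervals,
unsorted event lists); ``ConfigError`` covers contradictory run configuration
(CLI exit code 1).
"""


class EEGRCNNError(Exception):
    """Base class for all package errors."""


class DataError(EEGRCNNError):
    """Unreadable or malformed input data."""


class ValidationError(DataError):
    """Input parsed but violates a documented invariant."""


class ConfigError(EEGRCNNError):
    """Contradictory or incomplete run configuration."""
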