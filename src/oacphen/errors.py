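"""Exception hierarchy.

``ConfigurationError`` maps to CLI exit code 2, ``DataError`` (and its
subclasses) to exit code 3.
"""


class OacphenError(Exception):
    """Base class for package errors."""


class ConfigurationError(OacphenError):
    """Invalid configuration: bad probability, unnormalized pmf, bad spec."""


class DataError(OacphenError):
    """Invalid or inconsistent data."""


class TablesIOError(DataError):
    """Unreadable or malformed table file; message names file and row."""


class LinkageError(DataError):
    """Records reference patients missing from the roster, or label sets differ."""


class UndefinedMetricError(OacphenError):
    """A test characteristic has a zero denominator (e.g. no reference positives)."""
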