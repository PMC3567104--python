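"""Exception hierarchy.

All package errors derive from :class:`IdpcmpError`.  ``ConfigError`` marks a
problem with user-supplied parameters or configuration (CLI exit code 2),
``DataError`` a problem with the content of an input file or an inconsistent
in-memory dataset (CLI exit code 3).  Both subclass :class:`ValueError` so
callers can catch them generically.
"""


class IdpcmpError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(IdpcmpError, ValueError):
    """Invalid parameter or configuration value."""


class DataError(IdpcmpError, ValueError):
    """Malformed or inconsistent input data."""
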