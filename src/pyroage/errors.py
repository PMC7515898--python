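"""Exception hierarchy.

``ValidationError`` covers bad user input (tables, configs, arguments);
``FormatError`` is the subset raised while parsing files. Runtime failures
inside fits use plain exceptions and are caught per-record by the search.
"""


class PyroageError(Exception):
    """Base class for all package errors."""


class ValidationError(PyroageError):
    """Invalid input data, configuration or argument."""


class FormatError(ValidationError):
    """Malformed input file (missing column, bad dialect, ...)."""
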