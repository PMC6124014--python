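"""Exception hierarchy shared across the package.

All errors derive from :class:`RasproError` so callers can catch the whole
family; the concrete classes also subclass the closest builtin (``ValueError``
or ``KeyError``) so generic handling keeps working.
"""


class RasproError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RasproError, ValueError):
    """A configuration or call parameter violates its contract."""


class InvalidInputError(RasproError, ValueError):
    """Input data (series, windows, cohorts) violates a precondition."""


class NoConsensusError(RasproError, ValueError):
    """A consensus symbol was requested on an empty observation window."""


class ConfigurationError(RasproError, KeyError):
    """Referential problems in a run configuration (unknown sensor etc.)."""


class ParseError(RasproError, ValueError):
    """A file did not match its declared dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CodecOverflowError(RasproError, ValueError):
    """An encoded motif exceeds the transport size budget."""


class DependencyError(RasproError, ValueError):
    """A tiered data product was requested before its inputs were computed."""
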