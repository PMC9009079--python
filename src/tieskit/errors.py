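"""Exception hierarchy shared across the toolkit."""


class TiesError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(TiesError):
    """Invalid configuration value (unknown strategy, bad format, ...)."""


class StructureError(TiesError):
    """A molecular graph, mapping or hybrid violates a structural invariant."""


class IOFormatError(TiesError):
    """A file does not conform to the expected dialect.

    Carries ``path`` and ``line`` (1-based, or None) for diagnostics.
    """

    def __init__(self, message: str, path=None, line=None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class DegenerateDataError(TiesError):
    """Input data carry no usable signal (constant array, empty series, ...)."""
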