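"""Exception hierarchy.

``ParameterError`` and ``SchemaError`` subclass :class:`ValueError` so callers
that do not care about the distinction can catch the builtin.
"""


class MempartError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MempartError, ValueError):
    """An argument is outside its documented valid range."""


class SchemaError(MempartError, ValueError):
    """A file or table does not match its documented layout."""


class ParseError(SchemaError):
    """A text table could not be parsed; the message cites the line number."""


class StateError(MempartError, RuntimeError):
    """An operation was called on an object in the wrong state
    (e.g. a feature extracted from an unreferenced free-energy profile)."""


class DisconnectedWindowsError(MempartError, ValueError):
    """Umbrella windows form histogram islands with no mutual overlap,
    so their free energies cannot be placed on a common scale."""

    def __init__(self, groups):
        self.groups = [sorted(g) for g in groups]
        super().__init__(
            "umbrella windows do not overlap into a single connected set; "
            f"disconnected window groups (by index): {self.groups}"
        )


class StageError(MempartError, RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
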