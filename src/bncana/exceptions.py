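"""Exception hierarchy shared across the package."""


class BNCanaError(Exception):
    """Base class for all package-specific errors."""


class CapacityError(BNCanaError):
    """An exhaustive computation was requested beyond its configured size limit."""


class CnetParseError(BNCanaError):
    """A ``.cnet`` file violates the dialect; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StructuralError(BNCanaError):
    """Inconsistent wiring, pattern lengths, or node references."""


class FixtureNotFoundError(BNCanaError, KeyError):
    """Requested example network is not packaged."""
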