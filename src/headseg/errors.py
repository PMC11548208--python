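"""Exception taxonomy.

Every error raised by the package derives from :class:`HeadsegError` so callers
can catch the package's failures as one family.  The CLI maps the subfamilies
to exit codes (configuration -> 2, data -> 3, anything else -> 4).
"""


class HeadsegError(Exception):
    """Base class for all errors raised by headseg."""


class ConfigurationError(HeadsegError, ValueError):
    """Invalid configuration: violated invariant, unattainable design, bad flag."""


class DataError(HeadsegError, ValueError):
    """Invalid or inconsistent input data."""


class EmptyInputError(DataError):
    """An operation received an empty frame source, signal, or score list."""


class ShapeError(DataError):
    """Array shapes violate an operation's contract."""


class UnknownLabelError(DataError):
    """A categorical label outside the recognised vocabulary."""


class OverlappingEventsError(DataError):
    """Movement events overlap, violating the session invariant."""
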