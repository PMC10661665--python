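"""Exception hierarchy.

All errors raised by the library derive from :class:`StvError` so callers can
catch the package's failures with a single ``except`` clause.
"""


class StvError(Exception):
    """Base class for all stvrepol errors."""


class ParameterError(StvError, ValueError):
    """An argument violates a documented precondition."""


class GenerationError(StvError):
    """The synthetic generator cannot realise the requested configuration."""


class InsufficientDataError(StvError):
    """Too few beats / values to compute the requested quantity."""


class ChannelNotFoundError(StvError, KeyError):
    """A channel label is not present in the record."""


class NoChannelError(StvError):
    """No electrogram channel passes the quality gates.

    Carries ``reasons``: a mapping of channel label to the textual reason it
    was rejected.
    """

    def __init__(self, message: str, reasons: dict | None = None):
        super().__init__(message)
        self.reasons = reasons or {}


class FormatError(StvError, ValueError):
    """A waveform or annotation file cannot be parsed, or the format is unsupported."""
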