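"""Exception types shared across the package.

All domain errors derive from :class:`BlinkSSAError` (itself a ``ValueError``)
so callers can catch either the specific condition or anything the package
raises on bad input.
"""


class BlinkSSAError(ValueError):
    """Base class for all blinkssa domain errors."""


class InvalidWindowError(BlinkSSAError):
    """Embedding window length outside the valid range [2, N]."""


class DegenerateSignalError(BlinkSSAError):
    """An operation received an all-zero / constant signal it cannot process."""


class DegenerateWindowError(BlinkSSAError):
    """A feature is undefined on a constant window (zero variance)."""


class DegenerateClusteringError(BlinkSSAError):
    """More clusters requested than there are distinct feature columns."""


class ChannelNotFoundError(BlinkSSAError):
    """Requested channel is absent from the recording."""


class MissingSamplingRateError(BlinkSSAError):
    """No sampling rate in the file and no override supplied."""
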