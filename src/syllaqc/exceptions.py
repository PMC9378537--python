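"""Exception hierarchy for syllaqc.

All package-specific failures derive from :class:`SyllaQCError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class SyllaQCError(Exception):
    """Base class for all syllaqc errors."""


class EmptyAudioError(SyllaQCError):
    """Raised when an audio stream contains no samples."""


class ShortSignalError(SyllaQCError):
    """Raised when a signal is shorter than one analysis window."""


class NoSpeechError(SyllaQCError):
    """Raised when a statistic requires detected speech but none was found."""


class DegenerateInputError(SyllaQCError):
    """Raised for zero-variance or otherwise degenerate statistical input."""
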