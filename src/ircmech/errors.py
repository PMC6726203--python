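"""Exception hierarchy shared by all analysis stages."""


class IrcmechError(Exception):
    """Base class for all package errors."""


class PathFormatError(IrcmechError):
    """Malformed trajectory / table input (bad frame, bad line, bad layout)."""


class ValidationError(IrcmechError):
    """Input parsed but violates a data-model invariant."""


class InsufficientDataError(IrcmechError):
    """An operation requires more frames/events than were supplied."""


class SpecError(IrcmechError):
    """A synthetic-path specification is internally inconsistent."""


class ConsistencyError(IrcmechError):
    """Cross-channel inputs disagree (e.g. frame counts differ)."""
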