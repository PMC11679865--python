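"""Exception hierarchy for affectlstm.

All package-specific failures derive from :class:`AffectLSTMError` so callers
can catch one base class at pipeline boundaries.
"""


class AffectLSTMError(Exception):
    """Base class for all affectlstm errors."""


class FormatError(AffectLSTMError):
    """A file is missing a required entry or is not in a recognised dialect."""


class ShapeError(AffectLSTMError):
    """An array has the wrong shape; message reports expected vs found."""


class ChannelError(AffectLSTMError):
    """A requested channel name is absent from the montage."""


class LengthError(AffectLSTMError):
    """A trial or segment is too short, or not a multiple of the window."""


class VersionError(AffectLSTMError):
    """An on-disk container declares an unknown layout version."""


class DegenerateChannelError(AffectLSTMError):
    """A channel is constant and the epsilon guard is disabled."""


class DomainError(AffectLSTMError):
    """A value lies outside its documented domain (e.g. a rating not in [1, 9])."""


class OptimizationError(AffectLSTMError):
    """The swarm could not be started (e.g. every initial fitness non-finite)."""
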