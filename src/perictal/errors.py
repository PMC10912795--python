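"""Exception hierarchy shared across the package.

Everything derives from :class:`PerictalError` so callers can catch one
base class; subclasses also derive from ``ValueError`` where the failure
is an invalid argument, keeping plain-Python idioms working.
"""


class PerictalError(Exception):
    """Base class for all package errors."""


class ValidationError(PerictalError, ValueError):
    """An argument or configuration violates a documented precondition."""


class FormatError(PerictalError, ValueError):
    """A file on disk is malformed or uses an unsupported layout."""


class BoundsError(PerictalError, ValueError):
    """A requested time interval falls outside the recording extent."""


class ScheduleError(PerictalError, ValueError):
    """A stimulation schedule is internally inconsistent (packages overlap)."""


class FilterError(PerictalError, ValueError):
    """A band-pass filter cannot be designed for the requested band."""


class InsufficientDataError(PerictalError, ValueError):
    """Not enough data to evaluate a statistic (e.g. an empty phase bin)."""
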