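"""Exception hierarchy.

Every error raised by this package derives from :class:`HypercohError` so
callers can catch the package's failures with one clause.  Readers and
validators always name the offending entity (channel, column, row, stage)
in the message.
"""


class HypercohError(Exception):
    """Base class for all hypercoh errors."""


class ParameterError(HypercohError, ValueError):
    """A parameter value violates its documented constraints."""


class FormatError(HypercohError, ValueError):
    """A file does not conform to the expected dialect."""


class DataQualityError(HypercohError):
    """Data parsed correctly but fails a quality rule (e.g. long NaN runs)."""


class AlignmentError(HypercohError):
    """Two series that must share a time base do not."""


class DegenerateInputError(HypercohError, ValueError):
    """Input is degenerate for the requested operation (e.g. zero variance)."""
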