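"""Exception and warning hierarchy."""


class ToneTraceError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ToneTraceError):
    """A file does not conform to the expected on-disk format."""


class DialectError(ToneTraceError):
    """A column-mapping dialect does not match the table at hand."""


class EmptyInputError(ToneTraceError):
    """An operation received no usable data."""


class IrreparableContourError(ToneTraceError):
    """Fewer than two valid F0 samples remain; the trial must be excluded."""


class DegenerateRangeError(ToneTraceError):
    """A speaker's pitch range has xmin == xmax."""


class RangeViolationError(ToneTraceError):
    """A sample falls outside the speaker range under strict normalization."""


class IncompleteReferenceError(ToneTraceError):
    """The target reference set is missing at least one tone category."""


class InsufficientDataError(ToneTraceError):
    """Too few observations for the requested operation."""


class ValidationError(ToneTraceError):
    """A label or parameter fails its domain constraints."""


class ClampWarning(UserWarning):
    """A value was clamped into its admissible range."""


class DegenerateClusteringWarning(UserWarning):
    """All contours are identical; clustering cannot separate them."""
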