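"""Exception hierarchy.

All package-specific failures derive from :class:`TditraceError` so callers
can catch one base class; the CLI maps subclasses to distinct exit codes.
"""


class TditraceError(Exception):
    """Base class for all package errors."""


class FormatError(TditraceError):
    """A file is not a decodable image or violates an expected schema."""


class CalibrationError(TditraceError):
    """Degenerate axis calibration (duplicate reference pixels, etc.)."""


class ContractError(TditraceError):
    """A precondition on an operation's arguments was violated."""


class EmptySignalError(TditraceError):
    """No signal pixels were found in the image."""


class CannotSegmentError(TditraceError):
    """Too few zero crossings to cut the trace into cycles."""


class RenderError(TditraceError):
    """Synthetic waveform does not fit inside the requested image."""


class SchemaError(FormatError):
    """CSV header or column-count mismatch against the dataset schema."""
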