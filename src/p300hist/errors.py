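"""Exception hierarchy for the p300hist package."""


class P300HistError(Exception):
    """Base class for all package errors."""


class FormatError(P300HistError):
    """A file does not follow the expected tabular session layout."""


class SessionValidationError(P300HistError):
    """A session violates a structural invariant (e.g., a non-permutation
    intensification sequence)."""


class UnsupportedFormatError(P300HistError):
    """An optional adapter was given a file it cannot interpret."""


class InvalidRateError(P300HistError):
    """The sampling rate is too low for the requested decimation."""


class DegenerateSignalError(P300HistError):
    """A constant signal cannot be standardized (zero variance)."""


class NoSequencesError(P300HistError):
    """A trial has no surviving intensification sequence."""


class EmptyPatchError(P300HistError):
    """The descriptor patch does not intersect the image."""


class CalibrationError(P300HistError):
    """Calibration preconditions are not met."""


class MissingTemplateError(P300HistError):
    """Letter identification was requested without a calibrated template set."""
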