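"""Exception hierarchy for drowsemeter.

Every error raised on purpose by the package derives from
:class:`DrowsemeterError`, so callers (and the CLI) can catch one type.
"""


class DrowsemeterError(Exception):
    """Base class for all drowsemeter errors."""


class StreamParseError(DrowsemeterError):
    """A stream file could not be parsed (names the offending line when known)."""


class StreamValidationError(DrowsemeterError):
    """A stream violates a structural invariant (e.g. non-monotone timestamps)."""


class InsufficientDataError(DrowsemeterError):
    """The stream is too short for the requested operation (calibration, windowing)."""


class CalibrationError(DrowsemeterError):
    """Calibration is impossible (no continuous measurements) or a profile is missing."""


class MissingCalibrationError(CalibrationError):
    """A continuous record was classified without a calibration profile."""


class ConfigError(DrowsemeterError):
    """A configuration file is malformed or violates an invariant."""


class MissingBackendError(ConfigError):
    """A landmark/face-detection backend or its model asset is unavailable."""


class DegenerateLandmarkError(DrowsemeterError):
    """Landmark geometry is degenerate (e.g. zero mouth width)."""


class NoRuleFiredError(DrowsemeterError):
    """All aggregated output degrees are zero (unreachable with a total rule base)."""


class CoverageError(DrowsemeterError):
    """Per-second output does not cover a ground-truth segment."""
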