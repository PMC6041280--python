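"""Exception hierarchy for the motorequiv pipeline.

Every stage raises a subclass of :class:`MotorEquivError` so callers can
distinguish pipeline failures from programming errors.
"""


class MotorEquivError(Exception):
    """Base class for all motorequiv pipeline errors."""


class ConfigurationError(MotorEquivError, ValueError):
    """Invalid simulation or analysis configuration."""


class FormatError(MotorEquivError, ValueError):
    """A file does not conform to the expected on-disk format."""


class SamplingError(MotorEquivError, ValueError):
    """Time base inconsistent with the declared sample rate, or too coarse."""


class DataError(MotorEquivError, ValueError):
    """Corrupt or unusable samples (NaN coordinates, occluded markers)."""


class ParameterError(MotorEquivError, ValueError):
    """A numeric parameter is outside its admissible range."""


class LengthError(MotorEquivError, ValueError):
    """A time series is too short for the requested operation."""


class SegmentationError(MotorEquivError, ValueError):
    """Movement cycles could not be detected in a recording."""


class SelectionError(MotorEquivError, ValueError):
    """Too few cycles detected to apply the cycle-selection rule."""


class ExtractionError(MotorEquivError, ValueError):
    """A kinematic landmark could not be computed for a cycle."""


class CompletenessError(MotorEquivError, ValueError):
    """A participant x tool x effector design cell is missing."""


class UndefinedCorrelationError(MotorEquivError, ValueError):
    """Correlation requested on a zero-variance vector."""
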