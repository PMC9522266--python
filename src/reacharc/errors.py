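"""Exception hierarchy for reacharc."""


class ReachArcError(Exception):
    """Base class for all reacharc errors."""


class DegenerateCalibrationError(ReachArcError):
    """Arm-length calibration from coincident headset/fingertip positions."""


class DegenerateGeometryError(ReachArcError):
    """A direction vector of zero length where an angle is required."""


class NoCrossingError(ReachArcError):
    """The fingertip trajectory never passed through the reach surface."""


class MissingConditionError(ReachArcError):
    """A session has no valid trials for a required condition."""


class InsufficientDataError(ReachArcError):
    """Too few observations for the requested computation."""


class NoInformationError(ReachArcError):
    """All paired differences are zero; the test carries no information."""


class DegenerateStatisticError(ReachArcError):
    """Zero-variance or otherwise degenerate input to a statistical test."""


class SchemaError(ReachArcError):
    """A file or configuration does not conform to the expected schema."""


class OrderingError(SchemaError):
    """Trial indices or timestamps are not properly ordered."""
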