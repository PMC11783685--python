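"""Exception hierarchy for poserom.

All library errors derive from :class:`PoseRomError` so callers (and the
CLI) can distinguish domain failures from programming errors.
"""


class PoseRomError(Exception):
    """Base class for all poserom errors."""


class FormatError(PoseRomError):
    """A file does not conform to the documented schema (e.g. missing column)."""


class ParseError(PoseRomError):
    """A row or field could not be parsed; message names the offending field."""


class IntegrityError(PoseRomError):
    """A uniqueness constraint was violated (duplicate measurement key)."""


class ValidationError(PoseRomError):
    """A value violates a domain invariant (range, enumeration, pairing)."""


class BlindingError(ValidationError):
    """The blinded-workflow guard failed: landmark annotations predate the
    measurement log they are supposed to be blinded to."""


class DegenerateGeometryError(PoseRomError):
    """Coincident or collinear keypoints make an angle undefined."""


class InvalidPostureError(PoseRomError):
    """Keypoints describe a posture the measurement model excludes
    (e.g. ankle at or above the knee for a rotation measurement)."""


class MissingKeypointError(PoseRomError):
    """A frame lacks a keypoint required by the requested movement."""


class FramingError(PoseRomError):
    """A projected skeleton falls outside the camera frame."""


class InsufficientDataError(PoseRomError):
    """Too few paired observations for the requested statistic."""


class UndefinedStatisticError(PoseRomError):
    """The statistic is undefined for the given data (e.g. zero variance)."""
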