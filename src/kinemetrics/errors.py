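"""Exception hierarchy for the kinemetrics pipeline."""


class KinemetricsError(Exception):
    """Base class for all package-specific errors."""


class ParseError(KinemetricsError):
    """A keypoint file could not be parsed; the message names the first bad record."""


class SchemaError(KinemetricsError):
    """A record uses an unknown joint label or is missing required columns."""


class AmbiguityError(KinemetricsError):
    """Multiple person detections in a frame and no selection rule configured."""


class ValidationError(KinemetricsError):
    """A parameter is outside its documented range."""


class DegenerateGeometryError(KinemetricsError):
    """Coincident keypoints make a joint angle undefined."""


class SmoothingError(KinemetricsError):
    """Too few observed frames to fit the local regression."""


class InsufficientDataError(KinemetricsError):
    """A series is too short for the requested computation."""


class ConfigError(KinemetricsError):
    """A synthetic-cohort configuration is internally inconsistent."""
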