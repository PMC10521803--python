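"""Exception hierarchy for the craniometrics pipeline.

Every stage raises a subclass of :class:`CraniometricsError` so callers can
distinguish pipeline failures from programming errors.
"""


class CraniometricsError(Exception):
    """Base class for all craniometrics errors."""


class InputError(CraniometricsError):
    """Unreadable, empty, or malformed input file."""


class SchemaError(CraniometricsError):
    """Structured input does not match the expected schema."""


class GeometryError(CraniometricsError):
    """Geometric precondition violated (collinear landmarks, invalid contour...)."""


class EmptySectionError(GeometryError):
    """A cutting plane does not intersect the mesh."""


class OpenContourError(GeometryError):
    """Plane section produced only open chains (non-watertight region)."""


class OrientationError(GeometryError):
    """Slice search found no usable cranial-side slice."""


class SamplingError(GeometryError):
    """Contour cannot be resampled (e.g. not star-shaped about its centroid)."""

    def __init__(self, message, angle_rad=None):
        super().__init__(message)
        self.angle_rad = angle_rad


class VolumeError(CraniometricsError):
    """Volume estimation failed (mesh not closed after capping, ...)."""


class DomainError(CraniometricsError):
    """Numeric argument outside its mathematical domain."""


class FitError(CraniometricsError):
    """Degenerate regression / correlation problem."""


class ReferenceLookupError(CraniometricsError):
    """No growth-reference table for the requested measurement/sex."""


class InsufficientDataError(CraniometricsError):
    """Too few observations for the requested statistical procedure."""


class DegenerateRankError(CraniometricsError):
    """Rank-based statistic undefined (all observations tied)."""


class GenerationError(CraniometricsError):
    """Synthetic-head generation failed (e.g. resolution too low)."""


class PipelineError(CraniometricsError):
    """Wraps an error raised inside the measurement pipeline with its stage."""

    def __init__(self, stage, original):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original
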