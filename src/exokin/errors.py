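"""Exception hierarchy shared across the package."""


class ExokinError(Exception):
    """Base class for all package-specific errors."""


class InvalidTransformError(ExokinError):
    """Rotation matrix is not a proper orthonormal rotation."""


class ConfigurationError(ExokinError):
    """Unknown coordinate name or inconsistent solver/model configuration."""


class GeometryViolationError(ExokinError):
    """Relative frame rotation is incompatible with the joint axis."""


class ModelDefinitionError(ExokinError):
    """Segment/joint/marker layout violates a model invariant."""


class MissingMarkerError(ExokinError):
    """A required marker label is absent from a trajectory or frame."""


class UnderdeterminedFrameError(ExokinError):
    """Too few usable markers in a frame to pose the model."""


class SchemaError(ExokinError):
    """A file or trajectory lacks a required column/channel."""


class ValidationError(ExokinError):
    """A numeric argument is out of its admissible range."""


class ImplausibleStaticPoseError(ExokinError):
    """Static marker heights are not vertically ordered hip > knee > ankle."""
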