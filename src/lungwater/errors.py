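"""Exception hierarchy shared across the package."""


class LungWaterError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LungWaterError, ValueError):
    """Invalid parameter value (non-positive SD, out-of-range correlation, ...)."""


class GeometryError(LungWaterError):
    """Anatomy does not fit the requested voxel grid."""


class SegmentationError(LungWaterError):
    """A mask could not be derived from the image (no seed, empty volume, ...)."""


class InputError(LungWaterError, ValueError):
    """Inconsistent or degenerate inputs to an analysis operation."""
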