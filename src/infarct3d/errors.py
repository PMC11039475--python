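"""Exception types shared across the pipeline."""


class Infarct3dError(Exception):
    """Base class for all package-specific errors."""


class MetadataError(Infarct3dError):
    """Volume metadata missing or inconsistent (e.g. no voxel size)."""


class PlacementError(Infarct3dError):
    """A phantom structure could not be placed on the requested grid."""


class CapacityError(Infarct3dError):
    """Requested lesion load exceeds the parenchyma occupancy cap."""


class ScaleError(Infarct3dError):
    """Operation requested at a voxel scale where it is ill-defined."""


class ConfigurationError(Infarct3dError):
    """Invalid or inconsistent configuration."""


class GeometryError(Infarct3dError):
    """Invalid acquisition geometry (e.g. non-positive propagation distance)."""


class FieldOfViewError(Infarct3dError):
    """Sample does not fit inside the detector field of view."""


class CorrectionError(Infarct3dError):
    """Flat/dark correction impossible (degenerate reference frames)."""


class InsufficientDataError(Infarct3dError):
    """Not enough projections / samples for the requested operation."""


class CoordinateError(Infarct3dError):
    """A seed or index lies outside the volume."""


class InsufficientSampleError(Infarct3dError):
    """Statistical comparison requested on too few observations."""
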