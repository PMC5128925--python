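"""Exception hierarchy for stereotrack.

Every stage raises a subclass of :class:`StereotrackError` so pipeline
drivers can attach the stage name and input ids before re-raising.
"""


class StereotrackError(Exception):
    """Base class for all stereotrack errors."""


class DimensionalityError(StereotrackError):
    """Image does not have exactly 3 spatial dimensions."""


class FormatError(StereotrackError):
    """File is not a valid volume/table, or its affine is missing/singular."""


class GeometryError(StereotrackError):
    """Geometric precondition violated (degenerate landmarks, no dural
    crossing, electrode outside the grid, bad angles, ...)."""


class SegmentationError(StereotrackError):
    """Thresholding produced an empty or unusable mask."""


class RegistrationError(StereotrackError):
    """Optimizer failure or non-overlapping volumes."""


class AmbiguousAxisError(StereotrackError):
    """Principal-axis fit is ill-defined (near-isotropic voxel cloud)."""


class InputError(StereotrackError):
    """Malformed tabular input (missing pairs, duplicate ids, ...)."""


class ConfigurationError(StereotrackError):
    """Pipeline configuration invalid or referencing missing paths."""
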