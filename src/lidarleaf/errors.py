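"""Exception hierarchy for the lidarleaf pipeline."""


class LidarLeafError(Exception):
    """Base class for all lidarleaf errors."""


class FormatError(LidarLeafError):
    """A file does not conform to the expected dialect (shape mismatch,
    non-numeric cell, malformed header)."""


class GeometryError(LidarLeafError):
    """Scanner geometry is invalid or inconsistent with the data
    (wrong mode, missing rail kinematics, non-monotonic angle vectors)."""


class ParameterError(LidarLeafError):
    """A processing parameter is out of its valid range or a required
    criterion is unset."""


class DegenerateSegmentError(LidarLeafError):
    """A segment is too small or too flat for the requested trait
    estimator (fewer than the minimum points, collinear projection)."""


class FitError(LidarLeafError):
    """The midline least-squares fit is rank deficient."""
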