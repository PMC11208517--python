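"""Exception hierarchy for the pulmovent pipeline."""


class PulmoventError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PulmoventError):
    """A file or header field could not be interpreted."""


class GridMismatchError(PulmoventError):
    """Two volumes do not share a compatible voxel grid."""


class InvalidSpecError(PulmoventError):
    """A phantom or analysis specification violates its invariants."""


class InfeasibleSpecError(InvalidSpecError):
    """A phantom specification is valid but cannot be realised."""


class DeformationError(PulmoventError):
    """A synthetic deformation field is non-invertible."""


class SegmentationError(PulmoventError):
    """Lung segmentation produced an empty or pathological result."""


class RegistrationError(PulmoventError):
    """Deformable registration diverged or produced an unusable field."""


class CalibrationError(PulmoventError):
    """Threshold calibration received an unusable cohort."""


class DataError(PulmoventError):
    """A cohort manifest references missing or inconsistent data."""
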