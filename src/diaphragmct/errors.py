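"""Exception hierarchy for the diaphragm-index pipeline."""


class DiaphragmCTError(Exception):
    """Base class for all pipeline errors."""


class VolumeFormatError(DiaphragmCTError):
    """Unsupported or unreadable volume file format."""


class VolumeTypeError(DiaphragmCTError):
    """Voxel data type incompatible with the requested operation."""


class ParameterError(DiaphragmCTError, ValueError):
    """Invalid parameter value."""


class EmptySegmentationError(DiaphragmCTError):
    """A lung/lobe mask contains no foreground voxels."""


class ExtractionFailureError(DiaphragmCTError):
    """No coronal slice yielded a usable lung-diaphragm intersection arc.

    Carries the per-slice status log so the failure mode can be inspected.
    """

    def __init__(self, message: str, slice_log=None):
        super().__init__(message)
        self.slice_log = dict(slice_log or {})


class EmptySurfaceError(DiaphragmCTError):
    """A diaphragm surface with no voxels was passed where one is required."""


class DegenerateSurfaceError(DiaphragmCTError):
    """Surface footprint too small to support area estimation."""


class AlignmentError(DiaphragmCTError):
    """Two volumes expected on the same grid do not match."""
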