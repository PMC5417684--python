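"""Exception hierarchy for the octspeckle pipeline."""


class OctSpeckleError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(OctSpeckleError, ValueError):
    """A distribution or model parameter is outside its valid domain."""


class InsufficientDataError(OctSpeckleError, ValueError):
    """Too few samples or records for the requested computation."""


class FitFailureError(OctSpeckleError, RuntimeError):
    """Maximum-likelihood optimisation failed to converge from every start."""


class GeometryError(OctSpeckleError, ValueError):
    """A phantom geometry does not fit inside the requested raster."""


class SegmentationError(OctSpeckleError, RuntimeError):
    """Layer boundaries could not be identified in enough image columns."""


class ApexNotFoundError(OctSpeckleError, RuntimeError):
    """The epithelium curve has no axial minimum (no zero crossing)."""


class RoiOutOfTissueError(OctSpeckleError, ValueError):
    """The requested ROI crosses a layer boundary or the image edge."""


class LogCompressedError(OctSpeckleError, ValueError):
    """Linear intensities were required but the image is log-compressed."""


class SchemaError(OctSpeckleError, ValueError):
    """A cohort table is missing required columns."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"cohort table missing required columns: {self.missing}")
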