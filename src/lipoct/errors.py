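"""Exception hierarchy for the lipoct pipeline.

Every stage raises a subclass of :class:`LipoctError`, so callers (and the
command-line driver) can distinguish pipeline failures from programming
errors while still naming the offending stage in the message.
"""


class LipoctError(Exception):
    """Base class for all lipoct errors."""


class VolumeFormatError(LipoctError):
    """File is not in a supported volume format or cannot be parsed."""


class DimensionalityError(VolumeFormatError):
    """Payload is not a 3D scalar grid."""


class MetadataError(LipoctError):
    """Required geometry metadata (e.g. voxel size) missing or invalid."""


class AnisotropyError(MetadataError):
    """Voxel spacing is not isotropic; the pipeline requires one spacing."""


class AlignmentError(LipoctError):
    """Two grids that must share geometry do not."""


class GeometryError(LipoctError):
    """Phantom geometry is inconsistent (e.g. hotspot outside the tumor)."""


class SegmentationError(LipoctError):
    """Tumor segmentation failed (no foreground, no bimodality, ...)."""


class HistogramError(LipoctError):
    """Histogram construction or windowing precondition violated."""


class FitError(LipoctError):
    """Background Gaussian fit failed to converge."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class DegenerateFitError(FitError):
    """Fitted Gaussian collapsed (sigma below one bin width)."""


class InputError(LipoctError):
    """Invalid user-supplied parameter value."""


class ConfigurationError(LipoctError):
    """Run configuration is incomplete or inconsistent."""


class PipelineError(LipoctError):
    """A pipeline stage failed; message names the stage."""
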