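"""Exception hierarchy for the reconstruction pipeline.

Every stage raises a subclass of :class:`PipelineError`; the CLI maps these
onto exit codes (config 2, data 3, stage 4).
"""


class PipelineError(Exception):
    """Base class for all pipeline failures."""


class ConfigError(PipelineError):
    """Invalid or incomplete run configuration."""


class DataError(PipelineError):
    """Input data unreadable or inconsistent."""


class DimensionMismatchError(DataError):
    """Slices in a stack do not share raster dimensions."""


class RoiBoundsError(DataError):
    """Requested ROI extends outside the source raster."""


class ParameterError(PipelineError, ValueError):
    """An operation parameter is outside its valid domain."""


class StageError(PipelineError):
    """A pipeline stage failed on otherwise valid input."""


class AlignmentError(StageError):
    """Stack alignment impossible (e.g. every slice degenerate)."""


class EmptyStructureError(StageError):
    """Surface extraction requested for a label with no voxels."""


class PhantomSpecError(ConfigError):
    """Phantom specification violates its own feasibility constraints."""
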