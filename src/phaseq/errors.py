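"""Exception hierarchy for pipeline failures.

Every stage raises a subclass of :class:`PipelineError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class PipelineError(Exception):
    """Base class for all quantification-pipeline failures."""


class FormatError(PipelineError):
    """Unsupported image sample format (e.g. RGB or float TIFF input)."""


class DimensionError(PipelineError):
    """Array shapes incompatible for the requested operation."""


class ParameterError(PipelineError, ValueError):
    """Invalid parameter value for an operation or generator."""


class PlacementError(PipelineError):
    """Synthetic objects could not be placed without overlap."""


class CalibrationError(PipelineError):
    """A calibration (PSF, flat field, correction curve) could not be built."""


class BulkRegionError(PipelineError):
    """The bulk / unclustered region is empty after mask dilation."""


class ConfigurationError(PipelineError):
    """Missing or inconsistent configuration for a pipeline stage."""


class SegmentationError(PipelineError):
    """A required segmentation class (e.g. cytoplasm) is empty."""


class DegenerateBleachError(PipelineError):
    """FRAP trace has no bleach depth (prebleach <= postbleach intensity)."""


class FitError(PipelineError):
    """Nonlinear fit failed to converge from every start."""


class ModelSelectionError(PipelineError):
    """Nested-model comparison violated (the richer model fit worse)."""
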