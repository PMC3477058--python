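"""Typed errors raised by the retscreen pipelines."""


class RetscreenError(Exception):
    """Base class for all package errors."""


class InvalidImageError(RetscreenError, ValueError):
    """Input raster violates the image contract (shape, range, finiteness)."""


class ParameterError(RetscreenError, ValueError):
    """Algorithm parameter outside its documented valid range."""


class DiscNotFoundError(RetscreenError):
    """No optic-disc candidate could be isolated (e.g. pathologically flat image)."""


class NoMainVesselError(RetscreenError):
    """No vessel component emanates from the optic-disc neighborhood."""


class BoundaryEstimationError(RetscreenError):
    """A retinal-layer boundary could not be estimated from the image."""


class ConfigError(RetscreenError, ValueError):
    """Pipeline configuration failed validation; message names the field."""


class PipelineStageError(RetscreenError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
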