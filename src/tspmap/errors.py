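"""Exception hierarchy for tspmap.

All errors raised by the package derive from :class:`TspError` so callers
can catch one base class at pipeline boundaries (the CLI maps them to a
non-zero exit status).
"""


class TspError(Exception):
    """Base class for all tspmap errors."""


class ParameterError(TspError, ValueError):
    """Invalid model or algorithm parameter (non-positive shape/scale, ...)."""


class GeometryError(TspError, ValueError):
    """A region specification falls outside the voxel grid."""


class FormatError(TspError, ValueError):
    """An input file does not have the expected layout (e.g. 3D where 4D needed)."""


class MetadataError(TspError, ValueError):
    """Required acquisition metadata (TR, ...) missing and not overridden."""


class RegistrationError(TspError, RuntimeError):
    """Realignment failed; carries the offending volume index."""

    def __init__(self, message: str, volume_index: int | None = None):
        super().__init__(message)
        self.volume_index = volume_index


class MaskingError(TspError, RuntimeError):
    """Brain-mask construction produced an empty or invalid mask."""


class SeedError(TspError, ValueError):
    """Seed voxel outside the mask or with a degenerate (constant) series."""


class IterationError(TspError, RuntimeError):
    """Iterative reference refinement emptied the contributing-voxel mask."""

    def __init__(self, message: str, iteration: int, threshold: float):
        super().__init__(message)
        self.iteration = iteration
        self.threshold = threshold


class ShapeError(TspError, ValueError):
    """Mismatched array shapes between inputs that must share a grid."""


class MetricError(TspError, ValueError):
    """Invalid inputs to an evaluation metric (empty region, n too small, ...)."""
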