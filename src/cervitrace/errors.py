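"""Exception hierarchy for the cervitrace pipeline.

Every failure mode a caller may want to catch programmatically gets its own
class; all inherit from :class:`CervitraceError` so ``except CervitraceError``
catches anything raised by the package itself.
"""


class CervitraceError(Exception):
    """Base class for all cervitrace errors."""


class GeometryInfeasibleError(CervitraceError):
    """Requested target geometry cannot fit on the board."""


class DegenerateGeometryError(CervitraceError):
    """Collinear or otherwise degenerate corner configuration."""


class NumericDegeneracyError(CervitraceError):
    """A projective mapping sent a point to infinity (w ~ 0)."""


class CornerDetectionError(CervitraceError):
    """Fewer than four board-corner fiducials found in a frame.

    Carries ``frame_index`` when detection ran inside a video loop.
    """

    def __init__(self, message: str, frame_index: int | None = None):
        super().__init__(message)
        self.frame_index = frame_index


class InvalidInputError(CervitraceError):
    """A parameter violated its documented range (fps <= 0, negative SEM...)."""


class UnsegmentableTrialError(CervitraceError):
    """The dot never satisfied the start-dwell rule or never reached the end
    vertex; ``diagnostics`` holds what was observed."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InvalidWindowError(CervitraceError):
    """Trial window with non-positive duration."""


class UncomputableMetricError(CervitraceError):
    """Too few usable samples in the trial window to compute a metric."""


class PoolingError(CervitraceError):
    """A movement direction contributed zero QC-passing trials.

    ``directions`` lists the offending direction labels.
    """

    def __init__(self, message: str, directions: list | None = None):
        super().__init__(message)
        self.directions = directions or []


class DegenerateSampleError(CervitraceError):
    """Constant or zero-variance sample where variation is required."""


class TransformInfeasibleError(CervitraceError):
    """Ln transform requested on data that is not strictly positive."""


class InsufficientDataError(CervitraceError):
    """Sample too small for the requested statistic."""


class InvalidLabelsError(CervitraceError):
    """ROC labels contain a single class."""


class IncompleteMatrixError(CervitraceError):
    """Missing cells in a subjects x occasions reliability matrix."""
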