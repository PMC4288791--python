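"""Exception hierarchy for the gBSI pipeline.

Every stage of the pipeline raises one of these, so the CLI can surface a
stage-tagged message instead of a bare stack trace.
"""


class GbsiError(Exception):
    """Base class for all package errors."""


class GridError(GbsiError):
    """Two objects that must share one voxel grid do not."""


class ValidationError(GbsiError):
    """Input data violates a domain invariant (range, finiteness, shape)."""


class DegenerateInputError(GbsiError):
    """An input is formally valid but empty/constant where structure is required."""


class DegenerateRegionError(DegenerateInputError):
    """The boundary-shift region is empty (identical masks)."""


class WindowCollapseError(GbsiError):
    """An intensity clipping window has low >= high (overlapping tissue distributions)."""


class ConvergenceError(GbsiError):
    """An iterative fit did not converge within its iteration cap."""


class FitError(GbsiError):
    """A regression/fit is degenerate (e.g. zero variance in the predictors)."""


class DomainError(GbsiError):
    """Values outside the mathematical domain of an operation (e.g. log of <= 0)."""


class StageError(GbsiError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[stage: {stage}] {cause}")
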