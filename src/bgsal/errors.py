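"""Exception types shared across the package."""


class BgsalError(Exception):
    """Base class for all package errors."""


class SizingError(BgsalError):
    """Image or parameter dimensions are too small for the operation."""


class ShapeMismatchError(BgsalError):
    """Two arrays that must share a shape do not."""


class DisconnectedGraphError(BgsalError):
    """The superpixel graph is not connected (indicates an upstream bug)."""


class SolverError(BgsalError):
    """An iterative solver failed to converge."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter


class RefinerContractError(BgsalError):
    """An external mask refiner violated its (image, mask) -> mask contract."""


class StageError(BgsalError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
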