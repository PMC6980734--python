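"""Exception types shared across the package."""


class CircascreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CircascreenError):
    """Input table does not follow the expected dialect (e.g. missing column)."""


class EmptyInputError(CircascreenError):
    """An operation received no usable rows / profiles."""


class InsufficientCoverageError(CircascreenError):
    """Too few non-missing bins on the canonical grid to proceed."""


class DegenerateCurveError(CircascreenError):
    """A curve with zero range cannot be min-max normalized."""


class FitFailureError(CircascreenError):
    """Template fitting diverged; carries the residual when available."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class TrainingDivergedError(CircascreenError):
    """Training loss became non-finite; carries the last good model."""

    def __init__(self, message: str, model=None, history=None):
        super().__init__(message)
        self.model = model
        self.history = history


class InsufficientLinesError(CircascreenError):
    """A centre has too few mutant lines for a deviation distribution."""


class PipelineError(CircascreenError):
    """A pipeline stage failed; the stage name is attached for reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
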