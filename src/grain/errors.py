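"""Exception hierarchy shared by all pipeline stages."""


class GrainError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GrainError):
    """A file on disk does not conform to its expected text format."""


class ValidationError(GrainError):
    """An in-memory object violates a domain invariant."""


class ConvergenceError(GrainError):
    """An iterative procedure failed to converge within its iteration cap."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class PipelineError(GrainError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
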