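"""Exception types raised across the package."""


class NumericalDegeneracyError(RuntimeError):
    """A linear-algebra quantity became singular or non-positive where positivity is required."""


class ConvergenceError(RuntimeError):
    """An iterative procedure failed to converge within its iteration cap."""


class NonIdentifiableError(ValueError):
    """The data cannot identify the requested model parameters (e.g. one-category 2AFC responses)."""


class UndefinedCorrelationError(ValueError):
    """A correlation was requested on a zero-variance column."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage label."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
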