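"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input data violates a documented contract (bad records, missing rows)."""


class PositivityError(ValueError):
    """Propensity scores at or numerically beyond the {0, 1} boundary, or
    perfect separation in the exposure model; weights are undefined."""


class EstimationError(ValueError):
    """Invalid estimator input (empty arm, grid mismatch, bad horizon)."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for debugging."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
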