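"""Exception hierarchy.

Validation failures (bad user input or malformed data) are distinguished from
internal errors so the command line can map them to distinct exit codes
(2 for validation, 1 for anything else).
"""


class SettleflowError(Exception):
    """Base class for all package errors."""


class ValidationError(SettleflowError):
    """Input data or configuration violates a documented precondition."""


class UnreachableError(ValidationError):
    """A pair of settlements has no path on the road graph.

    Unreachable pairs are an error rather than a sentinel distance: an
    arbitrary large value would silently distort distance-decay calibration.
    """


class PipelineError(SettleflowError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
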