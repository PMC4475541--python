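"""Exception hierarchy used across the package."""


class RingdimError(Exception):
    """Base class for all package errors."""


class ConfigError(RingdimError):
    """Invalid or inconsistent configuration."""


class DomainError(RingdimError):
    """Input outside the mathematical domain of an operation."""


class ParseError(RingdimError):
    """Malformed input file."""


class AlignmentError(RingdimError):
    """Blocks cannot be aligned on a common sample list."""


class ConvergenceError(RingdimError):
    """Iterative fit failed to converge.

    Carries the component index (0-based) and the last observed change in
    the saliences so the caller can diagnose degenerate inputs.
    """

    def __init__(self, component: int, delta: float, max_iter: int):
        self.component = component
        self.delta = delta
        self.max_iter = max_iter
        super().__init__(
            f"component {component + 1} did not converge within {max_iter} "
            f"iterations (last max salience change {delta:.3e})"
        )


class PipelineError(RingdimError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
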