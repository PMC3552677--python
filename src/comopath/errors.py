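"""Exception hierarchy shared across the pipeline."""


class ComopathError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ComopathError, ValueError):
    """An input violates a documented precondition or invariant."""


class ParseError(ComopathError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DomainError(ComopathError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class PipelineStageError(ComopathError, RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
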