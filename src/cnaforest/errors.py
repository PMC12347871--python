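"""Exception hierarchy shared across the package."""


class CnaForestError(Exception):
    """Base class for all package errors."""


class FormatError(CnaForestError, ValueError):
    """A file does not conform to the documented dialect (missing column,
    unparseable row, duplicate key). Carries the offending line number when
    the problem is row-level."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(CnaForestError, ValueError):
    """An in-memory object violates a domain invariant."""


class ConfigError(CnaForestError, ValueError):
    """A configuration object is internally inconsistent."""


class MatchingError(CnaForestError, RuntimeError):
    """Reference matching is infeasible for the given pool."""


class PipelineError(CnaForestError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
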