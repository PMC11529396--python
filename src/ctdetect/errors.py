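"""Exception hierarchy shared across the package."""


class CtdetectError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CtdetectError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class ValidationError(CtdetectError):
    """Input data violates a documented invariant."""


class EmptyGroupError(CtdetectError):
    """A statistic was requested on an empty group of samples."""


class StageError(CtdetectError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
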