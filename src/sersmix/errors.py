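"""Exception types shared across the package."""


class SersmixError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(SersmixError, ValueError):
    """A configuration object is internally inconsistent or incompatible
    with the data it is applied to (e.g. a peak centre outside the grid)."""


class DegenerateInputError(SersmixError, ValueError):
    """An input is formally valid but degenerate for the requested
    operation (e.g. a constant spectrum under min-max normalization)."""


class ParseError(SersmixError, ValueError):
    """A spectral file could not be parsed; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class StageError(SersmixError, RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


class TrainingError(SersmixError, RuntimeError):
    """Model training diverged (non-finite loss); carries the epoch."""

    def __init__(self, message: str, epoch: int):
        super().__init__(f"{message} (epoch {epoch})")
        self.epoch = epoch
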