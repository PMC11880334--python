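"""Exception hierarchy shared across the package."""


class BurnscopeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BurnscopeError):
    """A file could be opened but is not a supported image/mask format."""


class ValidationError(BurnscopeError):
    """An input violates a documented contract (bad label code, bad shape...)."""


class DegeneracyError(BurnscopeError):
    """The data are too degenerate for the requested operation (rank-deficient
    channels, empty region, all pixels discarded...)."""


class StageError(BurnscopeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


class TrainingError(BurnscopeError):
    """Optimization diverged (non-finite loss)."""

    def __init__(self, epoch: int, message: str = "non-finite training loss"):
        self.epoch = epoch
        super().__init__(f"{message} at epoch {epoch}")
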