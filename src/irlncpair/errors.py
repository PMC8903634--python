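"""Exception hierarchy shared across the package."""


class IrlncpairError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(IrlncpairError, ValueError):
    """A file or table violates its declared format or invariants."""


class ConfigError(IrlncpairError, ValueError):
    """A configuration object or file is inconsistent."""


class UndefinedCorrelationError(IrlncpairError, ValueError):
    """Pearson correlation requested for a zero-variance vector."""


class DegenerateFitError(IrlncpairError, ValueError):
    """A survival model cannot be fit (no events, constant covariate, ...)."""


class NonConvergenceError(IrlncpairError, RuntimeError):
    """A likelihood maximization failed to converge (e.g. monotone likelihood)."""


class PipelineStageError(IrlncpairError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
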