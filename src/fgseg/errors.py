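"""Exception hierarchy for the pipeline."""


class FgsegError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FgsegError, ValueError):
    """A stimulus or pipeline configuration cannot be honored exactly."""


class FormatError(FgsegError, ValueError):
    """An image file has an unmappable pixel format."""


class ShapeError(FgsegError, ValueError):
    """Fields passed to an operation do not share geometry."""


class ConvergenceError(FgsegError, RuntimeError):
    """An iterative stage failed to converge.

    Carries the last residual in ``residual`` and the stage name in ``stage``.
    """

    def __init__(self, message: str, residual: float | None = None,
                 stage: str | None = None):
        super().__init__(message)
        self.residual = residual
        self.stage = stage


class NumericalError(FgsegError, RuntimeError):
    """A linear solve failed; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class InvalidSeedError(FgsegError, ValueError):
    """Flood-fill seed placed on a supra-threshold boundary pixel."""


class AnalysisError(FgsegError, ValueError):
    """Statistical analysis called on an unbalanced or degenerate design."""
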