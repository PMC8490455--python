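"""Exception hierarchy shared across the pipeline stages."""


class HeateconError(Exception):
    """Base class for all package errors."""


class ConfigError(HeateconError, ValueError):
    """Invalid configuration or invalid input values."""


class InsufficientDataError(HeateconError, ValueError):
    """A series does not cover the span an operation requires."""


class AlignmentError(HeateconError, ValueError):
    """Dates/grids of two inputs do not line up."""


class CoverageError(HeateconError, ValueError):
    """Required hours or days are missing within the analysis window."""


class ConvergenceError(HeateconError, RuntimeError):
    """An iterative solve failed to reach its tolerance; carries diagnostics."""

    def __init__(self, message: str, residual: float | None = None, iterations: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations
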