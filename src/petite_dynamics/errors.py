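"""Named exception types used across the package."""


class ValidationError(ValueError):
    """Input failed a documented precondition (shape, range, finiteness)."""


class UndefinedFractionError(ValidationError):
    """Mutant fraction requested where total abundance is zero (or underflowed)."""


class NoLinearRangeError(RuntimeError):
    """No contiguous OD600 window satisfied the log-linear fitting criteria."""


class UndefinedCorrelationError(ValidationError):
    """Pearson correlation requested for a zero-variance input."""


class CalibrationError(RuntimeError):
    """No colony-area cutoff satisfied the false-positive constraint.

    Carries the best infeasible candidate in ``best_candidate`` and its
    diagnostics in ``diagnostics``.
    """

    def __init__(self, message, best_candidate=None, diagnostics=None):
        super().__init__(message)
        self.best_candidate = best_candidate
        self.diagnostics = diagnostics


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; the optimizer trace is attached."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
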