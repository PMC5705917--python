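"""Exception hierarchy.

``ValidationError`` covers malformed inputs (CLI exit code 2);
``NumericalError`` covers fit failures and degenerate distributions
(CLI exit code 3).
"""


class TnscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(TnscreenError):
    """Malformed or inconsistent input data."""


class ConfigError(ValidationError):
    """Invalid parameter combination."""


class NumericalError(TnscreenError):
    """A numerical procedure failed."""


class DegenerateDistributionError(NumericalError):
    """Histogram fit requested on data with no spread."""


class FitConvergenceError(NumericalError):
    """Nonlinear least-squares fit did not converge.

    Carries the initial guess and data summary so the failure is
    diagnosable; never silently falls back to moments.
    """

    def __init__(self, message: str, p0=None, n_values: int | None = None):
        super().__init__(message)
        self.p0 = p0
        self.n_values = n_values
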