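"""Exception hierarchy for the PSM clock model."""


class PSMClockError(Exception):
    """Base class for all package errors."""


class ParameterError(PSMClockError, ValueError):
    """A parameter violates its domain (e.g. T0 <= 0, 1 + xi <= 0)."""


class MonotonicityError(ParameterError):
    """A period-gradient table decreases somewhere; names the offending pair."""

    def __init__(self, x_left: float, t_left: float, x_right: float, t_right: float):
        self.pair = ((x_left, t_left), (x_right, t_right))
        super().__init__(
            f"period gradient must be non-decreasing: T({x_left:g}) = {t_left:g} "
            f"> T({x_right:g}) = {t_right:g}"
        )


class DegenerateGradientError(PSMClockError):
    """A flat gradient (lambda = 0) makes the requested quantity undefined."""


class StagnationError(PSMClockError):
    """The threshold formation rule can never fire (phase difference static)."""


class ExhaustionError(PSMClockError):
    """Somite removal would leave fewer than two cells in the PSM."""


class ConvergenceError(PSMClockError):
    """An iterative solver did not reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)
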