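"""Exception types raised by the simulator and the equilibrium theory."""


class CoevostatError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CoevostatError, ValueError):
    """A parameter is outside its admissible domain."""


class ConsistencyError(CoevostatError, RuntimeError):
    """Internal state arrays disagree in shape or roster."""


class NumericalFailureError(CoevostatError, FloatingPointError):
    """Integration produced a non-finite state variable.

    Attributes
    ----------
    variable : str
        Name of the offending state variable (``"R"``, ``"N"`` or ``"V"``).
    step : int or None
        Index of the integration step at which the failure was detected.
    """

    def __init__(self, variable: str, step: int | None = None):
        self.variable = variable
        self.step = step
        at = f" at step {step}" if step is not None else ""
        super().__init__(f"non-finite value in state variable {variable!r}{at}")


class NoGrowthError(CoevostatError, ValueError):
    """The strain cannot grow at any resource concentration (gamma*delta <= omega)."""


class CannotEstablishError(CoevostatError, ValueError):
    """The strain's limiting resource concentration exceeds the supply."""


class UndefinedObservableError(CoevostatError, ValueError):
    """The requested observable is undefined for this community state."""
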