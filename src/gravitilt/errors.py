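"""Exception hierarchy for gravitilt."""


class GravitiltError(Exception):
    """Base class for all package-specific errors."""


class InvalidConditionError(GravitiltError):
    """A tilt condition violates a model precondition (e.g. G <= 0)."""


class SingularityError(GravitiltError):
    """The gravito-inertial force magnitude is zero; the gravity-direction
    normalization is undefined (0 G cannot be simulated)."""


class ConvergenceError(GravitiltError):
    """The observer failed to reach a steady state within the horizon."""

    def __init__(self, message, last_value=None, residual_rate=None):
        super().__init__(message)
        self.last_value = last_value
        self.residual_rate = residual_rate


class CalibrationError(GravitiltError):
    """Root-finding on the utricular weight failed."""


class UnidentifiableModelError(GravitiltError):
    """The requested fit is not identifiable from the data provided."""


class UndefinedRSquaredError(GravitiltError):
    """R-squared is undefined (zero total sum of squares)."""


class UnknownModelError(GravitiltError):
    """A model name is not in the static-model registry."""

    def __init__(self, name, registered):
        super().__init__(
            f"unknown model {name!r}; registered models: {sorted(registered)}"
        )
        self.registered = sorted(registered)


class SchemaError(GravitiltError):
    """An input table or file does not match the expected schema."""
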