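"""Exception types shared across the package."""


class ScalesymError(Exception):
    """Base class for package-specific errors."""


class DomainError(ScalesymError, ValueError):
    """An evaluation point lies outside the domain of the Lagrangian family.

    The power-series family carries real (generally non-integer, often
    negative) position exponents, so it is only real-valued for q > 0; driven
    terms with negative time exponents additionally require t > 0.
    """


class SingularDynamicsError(ScalesymError, ArithmeticError):
    """The equation-of-motion denominator is (numerically) zero.

    The closed-form acceleration divides by sum_{y>=2} y(y-1) C_y
    q^{(alpha-1)y} qdot^{y-2}; when this falls below the configured
    tolerance the acceleration is undefined.
    """


class UnsupportedModelError(ScalesymError, ValueError):
    """The operation requires a time-independent (z = 0) family."""


class CollisionError(ScalesymError, RuntimeError):
    """A simulated particle crossed the collision guard radius.

    Carries the partial trajectory integrated up to the failure, plus the
    time reached.
    """

    def __init__(self, message, time_reached=None, partial=None):
        super().__init__(message)
        self.time_reached = time_reached
        self.partial = partial
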