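"""Exception types shared across the package."""


class EcokitError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(EcokitError, ValueError):
    """A simulation or pipeline configuration violates an invariant."""


class NumericalDegeneracyError(EcokitError, ArithmeticError):
    """A covariance (or similar) matrix is numerically singular.

    Raised by the Gaussian Bhattacharyya distance when the pooled covariance
    cannot be inverted at shrinkage 0; the remedy is a positive shrinkage
    intensity.
    """


class ValidationError(EcokitError, ValueError):
    """An input table or matrix violates its contract."""
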