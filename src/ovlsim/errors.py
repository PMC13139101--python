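"""Exception hierarchy shared across the package."""


class OvlsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OvlsimError, ValueError):
    """A distribution or configuration parameter is outside its domain."""


class InvalidArgumentError(OvlsimError, ValueError):
    """A function argument violates a precondition (e.g. empty input)."""


class DegenerateSampleError(OvlsimError, ValueError):
    """A sample has zero spread where an estimator needs variability."""


class UndefinedStatisticError(OvlsimError, ValueError):
    """The requested statistic is undefined for this input (e.g. all ties)."""


class NumericalError(OvlsimError, RuntimeError):
    """A numerical routine (quadrature, root finding) failed to converge."""
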