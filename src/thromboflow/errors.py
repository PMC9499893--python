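"""Exception hierarchy for the thromboflow package."""


class ThromboflowError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ThromboflowError, ValueError):
    """A field, grid or parameter violates a model invariant."""


class StructuralError(ThromboflowError, ValueError):
    """An input file is malformed (e.g. a non-rectangular lattice)."""


class ConfigurationError(ThromboflowError, ValueError):
    """A configuration key, boundary label or region setup is invalid."""


class ParameterDomainError(ThromboflowError, ValueError):
    """Parameters put the activation power law outside its admissible domain."""


class InsufficientDataError(ThromboflowError, ValueError):
    """Too few data points for the requested statistic."""


class DegenerateRegressionError(ThromboflowError, ValueError):
    """Regression input is degenerate (constant predictor)."""


class NumericalError(ThromboflowError, RuntimeError):
    """A linear solve or other numerical kernel failed."""


class ModelCollapseError(ThromboflowError, RuntimeError):
    """The species system diverged: the activated fraction left [0, 1].

    Overly strong reaction sources (e.g. a chemical-activation threshold far
    below the ADP levels actually reached) drive the explicit source update
    past the physical bounds of the activated fraction.  The partial result
    accumulated before the collapse, if any, is attached as
    ``partial_result``.
    """

    def __init__(self, message: str, partial_result=None):
        super().__init__(message)
        self.partial_result = partial_result
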