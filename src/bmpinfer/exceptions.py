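"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation errors -> 2,
convergence/training failures -> 3, I/O problems -> 4.
"""


class BmpInferError(Exception):
    """Base class for all package errors."""


class ValidationError(BmpInferError, ValueError):
    """Invalid shapes, negative concentrations, bad configuration values."""


class SolverError(BmpInferError, RuntimeError):
    """Equilibrium solver failed to converge.

    Attributes
    ----------
    residual : float
        Worst conservation residual at the point of failure.
    context_index : int or None
        Index of the offending experiment when raised from a batched call.
    """

    def __init__(self, message, residual=None, context_index=None):
        super().__init__(message)
        self.residual = residual
        self.context_index = context_index


class TrainingError(BmpInferError, RuntimeError):
    """Surrogate or variational training produced a non-finite objective."""

    def __init__(self, message, epoch=None, trace=None):
        super().__init__(message)
        self.epoch = epoch
        self.trace = trace


class DegenerateWeightsError(BmpInferError, RuntimeError):
    """All importance weights underflowed to zero during resampling."""
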