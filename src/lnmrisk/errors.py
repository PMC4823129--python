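"""Exception hierarchy for lnmrisk."""


class LnmRiskError(Exception):
    """Base class for all lnmrisk errors."""


class ValidationError(LnmRiskError, ValueError):
    """Raised when an input violates a documented precondition."""


class ConvergenceError(LnmRiskError, RuntimeError):
    """Raised when an iterative model fit fails to converge."""


class CollinearityError(LnmRiskError, ValueError):
    """Raised when covariates supplied to a joint fit are linearly dependent."""
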