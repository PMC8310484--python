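"""Exception hierarchy shared across the package."""


class MVDLNMError(Exception):
    """Base class for package errors."""


class DataValidationError(MVDLNMError):
    """Raised when an input series violates the daily-series contract."""


class BasisError(MVDLNMError):
    """Raised when a spline or lag basis cannot be constructed."""


class ModelFitError(MVDLNMError):
    """Raised when a model cannot be fitted at all (as opposed to a
    non-converged fit, which is returned flagged)."""


class PoissonSupportError(ModelFitError):
    """Raised when a transformed outcome leaves the support of a Poisson
    mean model (negative values), e.g. PCA-weighted lagged counts."""
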