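"""Exception hierarchy for lfmcdyn."""


class LfmcError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(LfmcError, ValueError):
    """A curve or covariance parameter is outside its valid domain."""


class DegenerateDataError(LfmcError, ValueError):
    """Data carry no usable signal (e.g. constant response)."""


class InsufficientDataError(LfmcError, ValueError):
    """Too few observations for the requested operation."""


class LabelingError(LfmcError, ValueError):
    """An unknown factor level (leaf type, stratum, plot) was encountered."""


class SchemaError(LfmcError, ValueError):
    """Input table does not expose the required columns."""


class EmptyInputError(LfmcError, ValueError):
    """No usable rows after reading/validation."""


class NonStationaryError(LfmcError, ValueError):
    """ARMA coefficients violate stationarity/invertibility."""


class UnsupportedOrderError(LfmcError, ValueError):
    """Requested ARMA order is outside the supported set."""


class UnsupportedOperationError(LfmcError, ValueError):
    """Operation undefined for the fitted mean function."""


class ConvergenceError(LfmcError, RuntimeError):
    """Optimizer failed to converge; carries the best state seen so far."""

    def __init__(self, message, best_state=None):
        super().__init__(message)
        self.best_state = best_state
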