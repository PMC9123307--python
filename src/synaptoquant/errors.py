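"""Exception hierarchy shared by all pipeline stages."""


class SynaptoQuantError(Exception):
    """Base class for all package errors."""


class ParameterError(SynaptoQuantError, ValueError):
    """A simulation / analysis parameter violates its contract."""


class PlacementError(SynaptoQuantError, RuntimeError):
    """Synthetic objects could not be placed without violating a
    separation constraint."""


class ContractError(SynaptoQuantError, ValueError):
    """An operation precondition was violated (bad input data)."""


class QCRejection(SynaptoQuantError):
    """A recording failed quality control.

    Attributes
    ----------
    reason : str
        Machine-readable reason code, one of ``too_few_sweeps`` or
        ``high_series_resistance``.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


class CalibrationRangeError(SynaptoQuantError, ValueError):
    """Sample size outside the outlier-calibration range; recalibrate
    with a wider range."""


class ConvergenceError(SynaptoQuantError, RuntimeError):
    """MCMC failed its convergence diagnostic.

    Carries the offending diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
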