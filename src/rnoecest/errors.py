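"""Exception and warning types shared across the pipeline."""


class RnoeCestError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(RnoeCestError, ValueError):
    """A simulation spec violates its invariants (e.g. pool amplitudes > 1)."""


class InvalidInputError(RnoeCestError, ValueError):
    """Input data violates an operation's preconditions."""


class FitFailureError(RnoeCestError, RuntimeError):
    """A least-squares fit did not converge after multi-start.

    Carries the diagnostics dict from the last attempt in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnreliableFitError(RnoeCestError, RuntimeError):
    """A fit is formally possible but the data cannot support it
    (e.g. the WASSR minimum sits at the edge of the sampled grid)."""


class QuantificationError(RnoeCestError, ValueError):
    """Internal-standard quantification impossible (e.g. reference AUC <= 0)."""


class BoundaryFitWarning(UserWarning):
    """A fitted parameter is pinned at a bound."""


class IdentifiabilityWarning(UserWarning):
    """Fitted components are too close to be distinguished reliably."""


class ExtrapolationWarning(UserWarning):
    """A frequency shift required values outside the sampled range;
    edge values were extended flat."""


class TruncatedPeakWarning(UserWarning):
    """A simulated peak extends beyond the ppm axis and was truncated."""
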