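"""Exception hierarchy for gwnr.

All errors raised by the library derive from :class:`GwnrError` so callers
can catch one base class at the CLI boundary.
"""


class GwnrError(Exception):
    """Base class for all gwnr errors."""


class InvalidInputError(GwnrError, ValueError):
    """Malformed or non-finite input (bad knots, NaN predictors, bad alpha...)."""


class SingularDesignError(GwnrError):
    """The global design matrix is numerically rank deficient."""

    def __init__(self, message: str, dependent_columns=None):
        super().__init__(message)
        self.dependent_columns = list(dependent_columns or [])


class LocalSingularityError(GwnrError):
    """Q*'T W Q* is numerically singular at one regression location."""

    def __init__(self, location: int, message: str | None = None):
        self.location = location
        super().__init__(
            message
            or f"weighted normal-equations matrix is singular at location {location}; "
            "try a larger bandwidth or a non-compact kernel"
        )


class DegenerateWeightsError(GwnrError):
    """A weight row is identically zero (bandwidth too small for a compact kernel)."""

    def __init__(self, location: int):
        self.location = location
        super().__init__(
            f"all spatial weights are zero at location {location}; "
            "increase the bandwidth or switch to the gaussian kernel"
        )


class DegreesOfFreedomError(GwnrError):
    """Residual degrees of freedom gamma1 are non-positive (model saturates the data)."""


class DegenerateTestError(GwnrError):
    """The goodness-of-fit test is degenerate (tau1 or tau2 non-positive).

    Occurs when the local model does not dominate the global one numerically,
    e.g. under uniform weights where G coincides with L.
    """


class BandwidthSelectionError(GwnrError):
    """Every candidate bandwidth produced a degenerate or singular fit."""


class ScenarioError(GwnrError):
    """A Monte-Carlo scenario is misconfigured (e.g. too many degenerate replicates)."""
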