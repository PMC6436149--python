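"""Exception hierarchy shared across the package."""


class HydroTraitsError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HydroTraitsError, ValueError):
    """A value violates a precondition (non-finite, wrong sign, out of range)."""


class InsufficientDataError(HydroTraitsError, ValueError):
    """Too few observations to perform the requested analysis."""


class NonIdentifiableError(HydroTraitsError, ValueError):
    """The data cannot pin down the model parameters (degenerate design)."""


class FitError(HydroTraitsError, RuntimeError):
    """The optimiser failed to produce a usable solution."""


class NoTurgorLossPointError(HydroTraitsError, ValueError):
    """The parabola/line system has no admissible intersection."""
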