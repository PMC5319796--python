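"""Exception hierarchy shared across the package."""


class OriturnError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(OriturnError, ValueError):
    """A simulation or fit model was specified inconsistently."""


class FormatError(OriturnError, ValueError):
    """An input table violates the expected dialect."""


class InsufficientDataError(OriturnError, ValueError):
    """Too few points/traces/tracks to run the requested analysis."""


class DegenerateTraceError(OriturnError, ValueError):
    """A trace contains values that make normalization undefined."""


class FitError(OriturnError, RuntimeError):
    """A nonlinear fit failed to converge; carries the initial guess."""

    def __init__(self, message: str, initial_guess: dict | None = None):
        super().__init__(message)
        self.initial_guess = initial_guess or {}
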