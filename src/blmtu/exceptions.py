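"""Exception hierarchy.

All errors raised by this package derive from :class:`BLMTUError` so callers
can catch package failures with a single except clause while still
distinguishing bad inputs from numerical failures.
"""


class BLMTUError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BLMTUError, ValueError):
    """A value violates a documented precondition (negative concentration,
    nonpositive EC50, too few data points, ...)."""


class ConfigError(BLMTUError, ValueError):
    """A configuration references unknown species/constants or is internally
    inconsistent (missing columns, unit mismatches, unknown options)."""


class ConvergenceError(BLMTUError, RuntimeError):
    """An iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NonIdentifiableError(BLMTUError, ValueError):
    """The experimental design cannot identify the requested parameters.

    ``axis`` names the deficient design axis (e.g. ``"Mg"`` or ``"pH"``).
    """

    def __init__(self, message: str, axis: str | None = None):
        super().__init__(message)
        self.axis = axis


class DegenerateControlError(BLMTUError, ZeroDivisionError):
    """Control root growth equals the initial length, so relative net
    elongation is undefined."""


class FitError(BLMTUError, RuntimeError):
    """A nonlinear fit failed; carries the optimiser trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []
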