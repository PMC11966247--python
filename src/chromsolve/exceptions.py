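"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`ChromSolveError`, so callers (and the CLI) can catch one base class.
Domain errors on scalar inputs subclass :class:`ValueError` as well, matching
what numpy/scipy users expect from bad arguments.
"""


class ChromSolveError(Exception):
    """Base class for all errors raised by chromsolve."""


class ChromatogramParseError(ChromSolveError, ValueError):
    """A chromatogram table could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class EmptyDataError(ChromSolveError, ValueError):
    """Fewer than two samples — not a usable chromatogram."""


class WindowError(ChromSolveError, ValueError):
    """An integration window is empty or lies outside the sampled span."""


class DomainError(ChromSolveError, ValueError):
    """A scalar argument is outside the physically meaningful domain."""


class CalibrationError(ChromSolveError, ValueError):
    """Calibration input is degenerate, incomplete, or ambiguous."""


class UnsolvableSystemError(ChromSolveError, ValueError):
    """The response matrix is rank-deficient: concentrations are not unique."""


class ContractError(ChromSolveError, ValueError):
    """Two objects that must share an ordering (detectors, analytes) do not."""


class ConfigurationError(ChromSolveError, ValueError):
    """A simulation or run configuration is missing a required entry."""
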