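"""Exception hierarchy shared across the package."""


class HelixSwitchError(Exception):
    """Base class for all package errors."""


class ParameterError(HelixSwitchError, ValueError):
    """Invalid user-supplied parameter or precondition violation."""


class FitError(HelixSwitchError, RuntimeError):
    """Nonlinear fit failed to converge.

    Carries the best residual achieved so callers can decide whether a
    partially converged answer is usable.
    """

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class ClashError(HelixSwitchError, RuntimeError):
    """Built model contains a steric clash; names the offending residues."""

    def __init__(self, message: str, residues=()):
        super().__init__(message)
        self.residues = tuple(residues)


class ClosureError(HelixSwitchError, RuntimeError):
    """Turn hinge cannot bridge its endpoints."""


class FormatError(HelixSwitchError, ValueError):
    """Unparseable or malformed input file."""


class ResidueLookupError(HelixSwitchError, KeyError):
    """A requested residue is missing from one or more chains."""
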