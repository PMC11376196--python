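"""Exception hierarchy.

Everything raised for a malformed chemical model or input file derives from
:class:`TitrakitError`, so callers (and the CLI) can distinguish "your input
is wrong" (exit code 2) from "the optimiser did not converge" (exit code 3).
"""


class TitrakitError(Exception):
    """Base class for all titrakit-specific errors."""


class ModelDefinitionError(TitrakitError, ValueError):
    """The declarative model is inconsistent (duplicate complexes,
    rank-deficient spectral relationships, unknown state labels, ...)."""


class ParseError(TitrakitError, ValueError):
    """An input file could not be parsed.

    Parameters
    ----------
    message : str
    coordinates : tuple, optional
        (row, column) of the offending cell, when known.
    """

    def __init__(self, message, coordinates=None):
        if coordinates is not None:
            message = f"{message} (at row {coordinates[0]}, column {coordinates[1]})"
        super().__init__(message)
        self.coordinates = coordinates


class DomainError(TitrakitError, ValueError):
    """A numeric argument is outside its physical domain
    (non-positive equilibrium constant, Kn*s >= 1, ...)."""


class RankDeficiencyError(TitrakitError, ValueError):
    """The linear spectral problem is rank deficient; carries the names of
    the unidentifiable spectral variables."""

    def __init__(self, variables):
        self.variables = tuple(variables)
        super().__init__(
            "spectral variables are unidentifiable (rank-deficient design): "
            + ", ".join(self.variables)
        )


class ConvergenceError(TitrakitError, RuntimeError):
    """An optimisation failed to converge and no usable result exists."""
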