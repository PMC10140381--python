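"""Named error categories raised across the package."""


class MathanxError(Exception):
    """Base class for all package errors."""


class DomainError(MathanxError, ValueError):
    """An input violates a mathematical precondition (invalid parameter,
    empty population, fractional order outside (0, 1], control outside
    [0, 1], ...)."""


class GridMismatchError(MathanxError, ValueError):
    """Time grids of two objects that must share a grid do not match."""


class RootBracketError(MathanxError, ValueError):
    """A root finder was given a bracket over which the target function
    does not change sign."""


class NonEquilibriumError(MathanxError, ValueError):
    """A state passed to an equilibrium-only routine is not (numerically)
    a steady state of the dynamics."""


class NumericsError(MathanxError, RuntimeError):
    """A numerical procedure failed to converge within its resource cap."""
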