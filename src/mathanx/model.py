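"""Compartmental model of mathematics-anxiety transmission.

The population of higher-institution students is split into six
compartments: susceptible ``S``, protected ``P``, exposed ``E``,
anxiety-infected ``A``, permanently anxious ``Q`` and recovered ``R``.
Anxiety spreads by social contact at a standard-incidence rate

    lambda_n = beta * (A + phi * Q) / N,      N = S + P + E + A + Q + R,

so transmission depends on the *prevalence* of anxious students, not on
their absolute number.  The integer-order dynamics are a system of six
nonlinear ODEs; the Caputo fractional-order variant of order
``theta in (0, 1]`` is the same vector field with every rate ``p``
replaced by ``p**theta`` (including the dimensionless fractions, which is
how the fractional system is stated; see docs/methods.md), and reduces to
the integer-order system exactly at ``theta = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

from .errors import DomainError

__all__ = [
    "ModelParameters",
    "FractionalOrder",
    "StateVector",
    "Trajectory",
    "force_of_infection",
    "integer_rhs",
    "fractional_rhs",
    "integer_rhs_array",
    "COMPARTMENTS",
]

#: Compartment order used by every array-valued interface in the package.
COMPARTMENTS = ("S", "P", "E", "A", "Q", "R")

_FRACTIONS = ("epsilon", "kappa", "sigma")


@dataclass(frozen=True)
class ModelParameters:
    """The twelve named rates and fractions of the anxiety model.

    Parameters
    ----------
    Delta : float
        Recruitment rate of new students (students / time).
    mu : float
        Natural exit (mortality/turnover) rate (1 / time); must be > 0.
    psi : float
        Progression rate out of the exposed class (1 / time).
    epsilon : float
        Fraction of recruits entering the protected class, in [0, 1].
    kappa : float
        Efficiency of the protection mechanism, in [0, 1].
    gamma : float
        Treatment rate of anxiety-infected students (1 / time).
    omega : float
        Rate at which recovered students lose recovery (1 / time).
    rho : float
        Rate at which protected students lose protection (1 / time);
        effective loss occurs at ``(1 - kappa) * rho``.
    delta : float
        Progression rate to permanent anxiety (1 / time).
    sigma : float
        Fraction of exposed students exiting directly to recovery, [0, 1].
    phi : float
        Relative infectiousness of permanently anxious students (>= 0).
    beta : float
        Anxiety transmission rate (1 / time).
    """

    Delta: float
    mu: float
    psi: float
    epsilon: float
    kappa: float
    gamma: float
    omega: float
    rho: float
    delta: float
    sigma: float
    phi: float
    beta: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise DomainError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise DomainError(f"parameter {f.name} must be >= 0, got {v!r}")
        if self.mu <= 0:
            raise DomainError(f"mu must be > 0, got {self.mu!r}")
        if self.Delta <= 0:
            raise DomainError(f"Delta must be > 0, got {self.Delta!r}")
        for name in _FRACTIONS:
            v = getattr(self, name)
            if v > 1:
                raise DomainError(f"{name} is a fraction and must be <= 1, got {v!r}")

    def powered(self, order: "FractionalOrder | float") -> "ModelParameters":
        """Return the parameter set with every entry raised to ``theta``.

        The fractional-order vector field equals the integer-order vector
        field evaluated with these powered parameters, so this transform
        is the single place the order enters the dynamics.
        """
        theta = _as_theta(order)
        if theta == 1.0:
            return self
        return replace(
            self, **{f.name: getattr(self, f.name) ** theta for f in fields(self)}
        )

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{f.name: float(d[f.name]) for f in fields(cls)})


@dataclass(frozen=True)
class FractionalOrder:
    """Order ``theta`` of the Caputo derivative, constrained to (0, 1]."""

    theta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta <= 1.0) or not np.isfinite(self.theta):
            raise DomainError(f"fractional order must lie in (0, 1], got {self.theta!r}")


def _as_theta(order: FractionalOrder | float) -> float:
    if isinstance(order, FractionalOrder):
        return order.theta
    return FractionalOrder(float(order)).theta


@dataclass(frozen=True)
class StateVector:
    """Counts of students in each compartment (all non-negative)."""

    S: float
    P: float
    E: float
    A: float
    Q: float
    R: float

    def __post_init__(self) -> None:
        for name in COMPARTMENTS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DomainError(f"compartment {name} must be finite and >= 0, got {v!r}")

    @property
    def N(self) -> float:
        """Total number of students."""
        return self.S + self.P + self.E + self.A + self.Q + self.R

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.P, self.E, self.A, self.Q, self.R], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        y = np.asarray(y, dtype=float)
        if y.shape != (6,):
            raise DomainError(f"state array must have shape (6,), got {y.shape}")
        return cls(*y)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in COMPARTMENTS}

    @classmethod
    def from_dict(cls, d: dict) -> "StateVector":
        return cls(**{name: float(d[name]) for name in COMPARTMENTS})


@dataclass(frozen=True)
class Trajectory:
    """A solution path on a fixed time grid.

    ``states`` holds one row per grid point in compartment order
    ``S, P, E, A, Q, R``.  ``controls``/``adjoints`` are populated only by
    the optimal-control solver.  ``warnings`` records non-fatal solver
    diagnostics such as negativity excursions.
    """

    times: np.ndarray
    states: np.ndarray
    controls: np.ndarray | None = None
    adjoints: np.ndarray | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)
        if t.ndim != 1 or y.ndim != 2 or y.shape != (t.size, 6):
            raise DomainError(
                f"times/states shapes do not match: {t.shape} vs {y.shape}"
            )
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise DomainError("times must be strictly increasing")

    @property
    def totals(self) -> np.ndarray:
        """N(t) on the grid."""
        return self.states.sum(axis=1)

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_frame(self):
        """Trajectory as a pandas DataFrame with columns t, S..R, N."""
        import pandas as pd

        data = {"t": self.times}
        for i, name in enumerate(COMPARTMENTS):
            data[name] = self.states[:, i]
        data["N"] = self.totals
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Vector fields
# ---------------------------------------------------------------------------


def _check_positive_total(N: float) -> None:
    if not N > 0:
        raise DomainError(f"total population must be > 0 to evaluate incidence, got N={N!r}")


def force_of_infection(
    state: StateVector,
    params: ModelParameters,
    order: FractionalOrder | float = 1.0,
) -> float:
    """Standard-incidence force of infection ``beta^th (A + phi^th Q) / N``.

    At ``theta = 1`` this is the integer-order incidence exactly.  The
    incidence is scale-free: multiplying every compartment by c > 0
    leaves it unchanged.
    """
    theta = _as_theta(order)
    N = state.N
    _check_positive_total(N)
    return (params.beta**theta) * (state.A + (params.phi**theta) * state.Q) / N


def integer_rhs_array(y: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Integer-order vector field on a raw 6-array (no state validation).

    Used by the solvers and finite-difference Jacobians, which must be
    able to probe states with small negative components.
    """
    S, P, E, A, Q, R = y
    N = S + P + E + A + Q + R
    _check_positive_total(N)
    lam = p.beta * (A + p.phi * Q) / N
    loss = (1.0 - p.kappa) * p.rho
    return np.array(
        [
            (1.0 - p.epsilon) * p.Delta + p.omega * R + loss * P - (lam + p.mu) * S,
            p.epsilon * p.Delta - (p.mu + loss) * P,
            lam * S - (p.mu + p.psi) * E,
            (1.0 - p.sigma) * p.psi * E - (p.mu + p.delta + p.gamma) * A,
            p.delta * A - p.mu * Q,
            p.gamma * A + p.sigma * p.psi * E - (p.mu + p.omega) * R,
        ]
    )


def integer_rhs(state: StateVector, params: ModelParameters) -> np.ndarray:
    """Six compartment derivatives of the integer-order model.

    The components sum to ``Delta - mu * N`` exactly (students enter at
    rate Delta and leave at per-capita rate mu; the infection terms only
    move students between compartments).
    """
    return integer_rhs_array(state.as_array(), params)


def fractional_rhs(
    state: StateVector,
    params: ModelParameters,
    order: FractionalOrder | float,
) -> np.ndarray:
    """Right-hand side of the Caputo fractional-order model.

    Identical to :func:`integer_rhs` with every parameter replaced by its
    theta-th power; at ``theta = 1`` the two coincide.  The component sum
    is ``Delta^theta - mu^theta * N`` exactly.
    """
    return integer_rhs_array(state.as_array(), params.powered(order))


def fractional_rhs_array(
    y: np.ndarray, params: ModelParameters, order: FractionalOrder | float
) -> np.ndarray:
    """Array variant of :func:`fractional_rhs` (no state validation)."""
    return integer_rhs_array(np.asarray(y, dtype=float), params.powered(order))
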