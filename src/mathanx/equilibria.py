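"""Equilibria, reproduction number, bifurcation and stability analysis.

The anxiety-free equilibrium (the model's disease-free analogue) has
closed form; the effective reproduction number R_eff is obtained both
from its closed-form expression and, as an internal cross-check, as the
spectral radius of the next-generation matrix F V^{-1} built over the
infected compartments (E, A, Q).

Endemic equilibria are found from the steady-state relations solved at a
fixed force of infection lambda*.  Summing the six steady-state equations
gives Delta^theta = mu^theta N*, so the endemic total is pinned at
N* = Delta^theta / mu^theta; substituting the reconstructed state into
the incidence definition then yields a scalar equation for lambda* whose
positive root (when R_eff > 1 it exists and is unique) is available in
closed form.  The sixteen auxiliary constants m1..m16 and the quadratic
coefficients (a2, a1, a0) of the transcribed endemic polynomial are also
reported: a0 is proportional to (1 - R_eff) exactly and serves as the
threshold indicator, but the transcribed quadratic's roots are not used
to locate equilibria (see docs/methods.md for why the reconstruction is
the authoritative route).

Local stability uses the Matignon condition: an equilibrium of a Caputo
system of order theta is locally asymptotically stable iff every
eigenvalue of the Jacobian satisfies |arg(lambda)| > theta * pi / 2.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, NonEquilibriumError, NumericsError, RootBracketError
from .model import (
    FractionalOrder,
    ModelParameters,
    StateVector,
    _as_theta,
    fractional_rhs_array,
    integer_rhs_array,
)

__all__ = [
    "ReffReport",
    "EndemicSolution",
    "StabilityReport",
    "anxiety_free_equilibrium",
    "effective_reproduction_number",
    "endemic_solve",
    "stability_assess",
    "critical_parameter",
    "endemic_constants",
    "matignon_margin",
]


# ---------------------------------------------------------------------------
# Anxiety-free equilibrium and R_eff
# ---------------------------------------------------------------------------


def anxiety_free_equilibrium(
    params: ModelParameters, order: FractionalOrder | float = 1.0
) -> StateVector:
    """Closed-form anxiety-free equilibrium (S0, P0, 0, 0, 0, 0).

    S0 + P0 = Delta^theta / mu^theta, the carrying total of the powered
    demography; the split between S0 and P0 is set by protected
    recruitment epsilon and protection loss (1 - kappa) rho.
    """
    p = params.powered(order)
    m2 = (1.0 - p.kappa) * p.rho
    m3 = p.mu + m2
    S0 = p.Delta * ((1.0 - p.epsilon) * p.mu + m2) / (p.mu * m3)
    P0 = p.epsilon * p.Delta / m3
    return StateVector(S0, P0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ReffReport:
    """Closed-form R_eff with its numeric next-generation-matrix cross-check."""

    D1: float
    S0: float
    P0: float
    closed_form: float
    ngm_numeric: float

    def __post_init__(self) -> None:
        if abs(self.closed_form - self.ngm_numeric) >= 1e-9 * max(1.0, self.closed_form):
            raise NumericsError(
                "closed-form R_eff and NGM spectral radius disagree: "
                f"{self.closed_form!r} vs {self.ngm_numeric!r}"
            )

    @property
    def value(self) -> float:
        return self.closed_form


def _ngm_spectral_radius(p: ModelParameters, S0: float, P0: float) -> float:
    """Spectral radius of F V^{-1} over the infected block (E, A, Q)."""
    frac = S0 / (S0 + P0)
    F = np.array(
        [
            [0.0, p.beta * frac, p.beta * p.phi * frac],
            [0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0],
        ]
    )
    V = np.array(
        [
            [p.mu + p.psi, 0.0, 0.0],
            [-(1.0 - p.sigma) * p.psi, p.mu + p.delta + p.gamma, 0.0],
            [0.0, -p.delta, p.mu],
        ]
    )
    K = F @ np.linalg.inv(V)
    return float(np.max(np.abs(np.linalg.eigvals(K))))


def effective_reproduction_number(
    params: ModelParameters, order: FractionalOrder | float = 1.0
) -> ReffReport:
    """Effective reproduction number of the fractional model.

    closed_form evaluates

        R_eff = beta^th (1-sigma^th) psi^th S0 (mu^th + phi^th delta^th)
                / (mu^th D1 (S0 + P0)),
        D1 = (mu^th + psi^th)(mu^th + delta^th + gamma^th),

    and ngm_numeric is the spectral radius of F V^{-1} at the anxiety-free
    equilibrium; construction of the report enforces their agreement.
    """
    p = params.powered(order)
    dfe = anxiety_free_equilibrium(params, order)
    S0, P0 = dfe.S, dfe.P
    D1 = (p.mu + p.psi) * (p.mu + p.delta + p.gamma)
    closed = (
        p.beta
        * (1.0 - p.sigma)
        * p.psi
        * S0
        * (p.mu + p.phi * p.delta)
        / (p.mu * D1 * (S0 + P0))
    )
    return ReffReport(
        D1=D1, S0=S0, P0=P0, closed_form=closed, ngm_numeric=_ngm_spectral_radius(p, S0, P0)
    )


# ---------------------------------------------------------------------------
# Endemic equilibria
# ---------------------------------------------------------------------------


def endemic_constants(
    params: ModelParameters, order: FractionalOrder | float = 1.0
) -> dict[str, float]:
    """The sixteen auxiliary constants m1..m16 of the endemic algebra."""
    p = params.powered(order)
    m = {}
    m["m1"] = (1.0 - p.epsilon) * p.Delta
    m["m2"] = (1.0 - p.kappa) * p.rho
    m["m3"] = p.mu + m["m2"]
    m["m4"] = p.mu + p.psi
    m["m5"] = (1.0 - p.sigma) * p.psi
    m["m6"] = p.mu + p.delta + p.gamma
    m["m7"] = p.mu + p.omega
    base = m["m3"] * m["m4"] * m["m6"] * m["m7"]
    m["m8"] = m["m1"] * base + m["m2"] * m["m4"] * m["m6"] * m["m7"] * p.epsilon * p.Delta
    m["m9"] = base - m["m5"] * p.omega * p.gamma - m["m6"] * p.sigma * p.omega * p.psi
    m["m10"] = base * p.mu
    m["m11"] = m["m4"] * m["m9"]
    m["m12"] = m["m4"] * m["m10"]
    m["m13"] = (
        m["m3"] * m["m4"] ** 2 * m["m6"] ** 2 * m["m7"]
        - m["m4"] * m["m5"] * m["m6"] * p.omega * p.gamma
        - m["m4"] * m["m6"] ** 2 * p.sigma * p.omega * p.psi
    )
    m["m14"] = m["m3"] * m["m4"] ** 2 * m["m6"] ** 2 * m["m7"] * p.mu
    m["m15"] = m["m13"] * p.mu
    m["m16"] = m["m14"] * p.mu
    return m


def _reconstruction_coeffs(p: ModelParameters) -> dict[str, float]:
    """Per-lambda coefficients of the steady-state reconstruction.

    With powered parameters p, at a fixed force of infection lambda the
    steady-state relations give P* = eps Delta / m3 and, proportional to
    lambda * S*:  E* = cE lam S*, A* = cA lam S*, Q* = cQ lam S*,
    R* = cR lam S*; the S-equation then closes the system.
    """
    m2 = (1.0 - p.kappa) * p.rho
    m3 = p.mu + m2
    m4 = p.mu + p.psi
    m6 = p.mu + p.delta + p.gamma
    m7 = p.mu + p.omega
    cE = 1.0 / m4
    cA = (1.0 - p.sigma) * p.psi / (m4 * m6)
    cQ = p.delta * cA / p.mu
    cR = (p.gamma * cA + p.sigma * p.psi * cE) / m7
    return {
        "P": p.epsilon * p.Delta / m3,
        "K": (1.0 - p.epsilon) * p.Delta + m2 * p.epsilon * p.Delta / m3,
        "cE": cE,
        "cA": cA,
        "cQ": cQ,
        "cR": cR,
        "cI": cA + p.phi * cQ,  # infectious weight in the incidence
        "d": 1.0 - p.omega * cR,  # S-denominator slope in lambda
    }


def _reconstruct_state(lam: float, p: ModelParameters) -> np.ndarray:
    c = _reconstruction_coeffs(p)
    S = c["K"] / (lam * c["d"] + p.mu)
    return np.array(
        [S, c["P"], c["cE"] * lam * S, c["cA"] * lam * S, c["cQ"] * lam * S, c["cR"] * lam * S]
    )


@dataclass(frozen=True)
class EndemicSolution:
    """Endemic-equilibrium analysis result.

    ``roots`` are the admissible positive force-of-infection values; each
    entry of ``equilibria`` is the corresponding steady state, with
    ``residual_norms`` the infinity norm of the vector field there.
    ``a2, a1, a0`` are the transcribed quadratic coefficients used as
    threshold diagnostics (a0 changes sign exactly at R_eff = 1).
    """

    m: dict[str, float]
    a2: float
    a1: float
    a0: float
    roots: tuple[float, ...]
    equilibria: tuple[StateVector, ...]
    residual_norms: tuple[float, ...]
    bifurcation_class: str
    reff: float = field(default=float("nan"))


def _transcribed_quadratic(
    params: ModelParameters, order: FractionalOrder | float, reff: float
) -> tuple[float, float, float]:
    """Quadratic coefficients as transcribed from the endemic algebra."""
    p = params.powered(order)
    m = endemic_constants(params, order)
    eD = p.epsilon * p.Delta
    m3, m4, m5, m6, m7 = m["m3"], m["m4"], m["m5"], m["m6"], m["m7"]
    m8, m9, m10, m13, m14 = m["m8"], m["m9"], m["m10"], m["m13"], m["m14"]
    a2 = (
        eD * m4 * m6 * m7 * p.mu * m9 * m13
        + m8 * m6 * m7 * m3 * p.mu * m13
        + m5 * m3 * m8 * m4 * m6 * m7 * p.mu * m9
        + m3 * m5 * m8 * p.delta * m4 * m6 * m7 * m9
        + m3 * m5 * p.gamma * m8 * p.mu * m13
        + m3 * m6 * p.sigma * p.psi * m8 * p.mu * m13
    )
    a1 = (
        m8 * m3 * m4 * m6 * m7 * p.mu * m13
        + eD * m4 * m6 * m7 * p.mu * m10 * m13
        + eD * m4 * m6 * m7 * p.mu * m9 * m14
        + m8 * m6 * m7 * m3 * p.mu * m14
        + m5 * m3 * m8 * m4 * m6 * m7 * p.mu * m10
        + m3 * m5 * m8 * p.delta * m4 * m6 * m7 * m10
        + m14 * m3 * m5 * p.gamma * m8 * p.mu
        + m3 * m6 * p.sigma * p.psi * m8 * p.mu * m14
        - p.beta * m3 * m5 * m8 * m4 * m6 * m7 * p.mu * m9
        - p.beta * p.phi * m3 * m5 * m8 * p.delta * m4 * m6 * m7 * m9
    )
    a0 = eD * m4 * m6 * m7 * p.mu * m10 * m14 * (1.0 - reff)
    return a2, a1, a0


def endemic_solve(
    params: ModelParameters,
    order: FractionalOrder | float = 1.0,
    incidence_tol: float = 1e-8,
) -> EndemicSolution:
    """Locate endemic equilibria and classify the bifurcation structure.

    The positive force-of-infection root is solved in closed form from
    the steady-state relations (at any equilibrium N* = Delta^th/mu^th,
    so lambda* satisfies a linear equation once the trivial lambda = 0
    branch is factored out).  Each candidate is reconstructed, checked
    for incidence self-consistency within ``incidence_tol`` relative and
    for non-negativity, and its vector-field residual is reported.

    Classification follows the sign pattern of (R_eff - 1) and the
    transcribed middle coefficient a1: ``unique_endemic`` when R_eff > 1,
    ``possibly_two_endemic`` when R_eff < 1 with a1 < 0, else
    ``no_endemic``.
    """
    theta = _as_theta(order)
    p = params.powered(theta)
    reff = effective_reproduction_number(params, theta).closed_form
    a2, a1, a0 = _transcribed_quadratic(params, theta, reff)
    if a2 <= 0:
        # the transcribed leading coefficient is claimed positive for all
        # admissible parameters, but its m9/m13 factors can turn negative
        # for strong recovery-loss; it is a diagnostic only, so flag it
        _warnings.warn(
            f"transcribed endemic quadratic has non-positive leading "
            f"coefficient a2={a2!r}; diagnostic only",
            stacklevel=2,
        )

    c = _reconstruction_coeffs(p)
    # N* = S*(1 + cT lam) + P* must equal beta^th cI lam S* / lam ... the
    # non-trivial branch reduces to S* = Delta^th / (mu^th beta^th cI):
    roots: list[float] = []
    states: list[StateVector] = []
    residuals: list[float] = []
    denom = p.beta * c["cI"]
    if denom > 0 and c["d"] != 0.0:
        S_star = p.Delta / (p.mu * denom)
        lam = (c["K"] - p.mu * S_star) / (c["d"] * S_star)
        if lam > 0:
            y = _reconstruct_state(lam, p)
            lam_check = p.beta * (y[3] + p.phi * y[4]) / y.sum()
            if abs(lam_check - lam) <= incidence_tol * max(lam, 1e-300) and np.all(
                y >= 0
            ):
                res = float(np.max(np.abs(integer_rhs_array(y, p))))
                roots.append(float(lam))
                states.append(StateVector.from_array(y))
                residuals.append(res)
            else:
                _warnings.warn(
                    f"candidate endemic root lambda*={lam!r} failed the incidence "
                    f"consistency check (got {lam_check!r}); dropped",
                    stacklevel=2,
                )

    if reff > 1.0:
        cls = "unique_endemic"
    elif a1 < 0.0:
        cls = "possibly_two_endemic"
    else:
        cls = "no_endemic"
    return EndemicSolution(
        m=endemic_constants(params, theta),
        a2=a2,
        a1=a1,
        a0=a0,
        roots=tuple(roots),
        equilibria=tuple(states),
        residual_norms=tuple(residuals),
        bifurcation_class=cls,
        reff=reff,
    )


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StabilityReport:
    """Matignon local-stability assessment at an equilibrium."""

    eigenvalues: np.ndarray
    theta: float
    matignon_stable: bool
    margin: float
    marginal: bool = False


def numeric_jacobian(
    y: np.ndarray, params: ModelParameters, order: FractionalOrder | float
) -> np.ndarray:
    """Central-difference Jacobian of the fractional vector field at y."""
    y = np.asarray(y, dtype=float)
    J = np.empty((6, 6))
    scale = max(1.0, float(np.abs(y).max()))
    h = 1e-6 * scale
    for j in range(6):
        e = np.zeros(6)
        e[j] = h
        J[:, j] = (
            fractional_rhs_array(y + e, params, order)
            - fractional_rhs_array(y - e, params, order)
        ) / (2.0 * h)
    return J


def matignon_margin(eigenvalues: np.ndarray, theta: float) -> float:
    """min over eigenvalues of |arg(lambda)| - theta*pi/2."""
    args = np.abs(np.angle(np.asarray(eigenvalues, dtype=complex)))
    return float(np.min(args) - theta * np.pi / 2.0)


def stability_assess(
    equilibrium: StateVector | np.ndarray,
    params: ModelParameters,
    order: FractionalOrder | float = 1.0,
    residual_tol: float = 1e-6,
) -> StabilityReport:
    """Assess local asymptotic stability of an equilibrium (Matignon).

    The Jacobian is computed by central finite differences of the
    fractional vector field.  Eigenvalues of magnitude below 1e-10, or
    with |arg| within 1e-10 of theta*pi/2, are marginal: the Matignon
    criterion is silent there, so the report flags them and declares the
    point not stable.
    """
    theta = _as_theta(order)
    y = equilibrium.as_array() if isinstance(equilibrium, StateVector) else np.asarray(equilibrium, float)
    N = float(y.sum())
    res = float(np.max(np.abs(fractional_rhs_array(y, params, theta))))
    if res >= residual_tol * max(N, 1.0):
        raise NonEquilibriumError(
            f"state is not an equilibrium: residual {res:.3g} "
            f"exceeds {residual_tol:.1g} * N"
        )
    eig = np.linalg.eigvals(numeric_jacobian(y, params, theta))
    margin = matignon_margin(eig, theta)
    tiny = np.abs(eig) < 1e-10
    marginal = bool(tiny.any() or abs(margin) < 1e-10)
    stable = (margin > 0.0) and not marginal
    return StabilityReport(
        eigenvalues=eig, theta=theta, matignon_stable=stable, margin=margin, marginal=marginal
    )


# ---------------------------------------------------------------------------
# Critical parameter values (R_eff = 1)
# ---------------------------------------------------------------------------


def critical_parameter(
    params: ModelParameters,
    order: FractionalOrder | float,
    name: str,
    bracket: tuple[float, float],
) -> float:
    """Parameter value at which the closed-form R_eff crosses 1.

    Solved by Brent bisection to 1e-10 relative accuracy.  Raises
    :class:`RootBracketError` when R_eff - 1 does not change sign over
    the bracket.  For ``name='beta'`` the scaling R_eff proportional to
    beta^theta gives the closed form beta* = beta * R_eff^(-1/theta),
    which the bisection result matches.
    """
    if name not in {f for f in ModelParameters.__dataclass_fields__}:
        raise DomainError(f"unknown parameter name {name!r}")
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise DomainError(f"bracket must satisfy lo < hi, got {bracket!r}")

    def g(value: float) -> float:
        trial = ModelParameters.from_dict({**params.to_dict(), name: value})
        return effective_reproduction_number(trial, order).closed_form - 1.0

    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise RootBracketError(
            f"R_eff - 1 does not change sign for {name} over [{lo}, {hi}] "
            f"(values {glo:.4g}, {ghi:.4g})"
        )
    return float(brentq(g, lo, hi, xtol=1e-14, rtol=1e-12))
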