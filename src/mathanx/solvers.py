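"""Numerical machinery: Mittag-Leffler evaluation and fixed-step solvers.

The Caputo initial-value problem  D^theta y = f(t, y), y(0) = y0  is
equivalent to the Volterra integral equation

    y(t) = y0 + (1 / Gamma(theta)) * int_0^t (t - s)^(theta - 1) f(s, y(s)) ds.

The default scheme discretizes this with a product-rectangle rule on a
uniform grid t_n = n h:

    y_n = y0 + (h^theta / Gamma(theta + 1))
              * sum_{j=0}^{n-1} [(n - j)^theta - (n - j - 1)^theta] f(t_j, y_j),

an explicit method with full power-law memory that collapses to classical
forward Euler when theta = 1 (all quadrature weights become 1).  A
memoryless one-step variant and a classical fixed-step RK4 reference are
also provided.  Grids are fixed-step only: the memory convolution makes
adaptivity expensive and non-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gamma as _gamma
from typing import Callable

import numpy as np

from .errors import DomainError, NumericsError
from .model import FractionalOrder, StateVector, Trajectory, _as_theta

__all__ = [
    "MittagLefflerParams",
    "SolverSettings",
    "mittag_leffler",
    "solve_caputo",
    "solve_classical",
]

SCHEMES = ("caputo_rectangle", "caputo_memoryless", "classical_rk")


@dataclass(frozen=True)
class MittagLefflerParams:
    """Arguments of the two-parameter Mittag-Leffler function."""

    theta1: float
    theta2: float = 1.0
    argument: float = 0.0
    tolerance: float = 1e-14

    def __post_init__(self) -> None:
        if not (self.theta1 > 0 and self.theta2 > 0):
            raise DomainError(
                f"Mittag-Leffler parameters must be positive, got "
                f"theta1={self.theta1!r}, theta2={self.theta2!r}"
            )
        if not self.tolerance > 0:
            raise DomainError(f"tolerance must be > 0, got {self.tolerance!r}")


def mittag_leffler(
    params: MittagLefflerParams | None = None,
    *,
    theta1: float | None = None,
    theta2: float = 1.0,
    argument: float | None = None,
    tolerance: float = 1e-14,
    max_terms: int = 10_000,
) -> float:
    """Evaluate E_{theta1,theta2}(t) = sum_{k>=0} t^k / Gamma(theta1 k + theta2).

    The series starts at k = 0, so E_{theta1,theta2}(0) = 1 / Gamma(theta2)
    and in particular E_theta(0) = 1, as the linear Caputo solution theory
    requires.  Summation stops once the running term magnitude stays below
    ``tolerance`` for three consecutive terms (the terms of this entire
    series are not monotone, so a single small term is not a safe stop).

    Accurate for the moderate arguments used in this package; large
    negative arguments of an alternating series would need a different
    algorithm and are rejected via the term cap.
    """
    if params is None:
        if theta1 is None or argument is None:
            raise DomainError("provide MittagLefflerParams or theta1= and argument=")
        params = MittagLefflerParams(theta1, theta2, argument, tolerance)
    t = params.argument
    total = 0.0
    term_ok = 0
    scale = max(1.0, abs(t))
    for k in range(max_terms):
        try:
            term = t**k / _gamma(params.theta1 * k + params.theta2)
        except OverflowError as exc:  # Gamma overflow => term underflows to 0
            raise NumericsError(f"Mittag-Leffler series overflow at k={k}") from exc
        total += term
        if abs(term) < params.tolerance * scale:
            term_ok += 1
            if term_ok >= 3:
                return total
        else:
            term_ok = 0
    raise NumericsError(
        f"Mittag-Leffler series did not converge within {max_terms} terms "
        f"for theta1={params.theta1}, theta2={params.theta2}, t={t}"
    )


@dataclass(frozen=True)
class SolverSettings:
    """Fixed-step grid and scheme selection.

    ``step`` is the grid spacing h, ``horizon`` the final time; the grid
    has ``round(horizon / step) + 1`` points.  ``negativity_tolerance``
    controls when a negative compartment excursion is recorded as a
    warning on the returned trajectory (the exact solution is positive,
    so excursions measure scheme error and are reported, never clipped).
    """

    step: float = 0.01
    horizon: float = 50.0
    scheme: str = "caputo_rectangle"
    negativity_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise DomainError(f"step must be > 0, got {self.step!r}")
        if self.step > self.horizon:
            raise DomainError(
                f"step ({self.step!r}) must not exceed horizon ({self.horizon!r})"
            )
        if self.scheme not in SCHEMES:
            raise DomainError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.step))

    def grid(self) -> np.ndarray:
        return self.step * np.arange(self.n_steps + 1, dtype=float)


def _as_y0(y0) -> np.ndarray:
    if isinstance(y0, StateVector):
        return y0.as_array()
    y = np.atleast_1d(np.asarray(y0, dtype=float))
    if y.ndim != 1:
        raise DomainError("initial state must be a 1-D vector or StateVector")
    return y


def caputo_weights(n: int, theta: float) -> np.ndarray:
    """Rectangle-rule memory weights w_k = (k+1)^theta - k^theta, k=0..n-1."""
    k = np.arange(n + 1, dtype=float)
    return k[1:] ** theta - k[:-1] ** theta


def caputo_step_array(
    f_of_index: Callable[[int, float, np.ndarray], np.ndarray],
    y0: np.ndarray,
    theta: float,
    h: float,
    n: int,
    memory: bool = True,
) -> np.ndarray:
    """Core stepping loop shared by the plain and control solvers.

    ``f_of_index(j, t_j, y_j)`` returns the vector field at grid node j,
    which lets callers bind grid-sampled controls by index.  Returns the
    (n+1, dim) array of states.
    """
    dim = y0.size
    c = h**theta / _gamma(theta + 1.0)
    ys = np.empty((n + 1, dim))
    ys[0] = y0
    F = np.empty((n, dim))
    if memory:
        w = caputo_weights(n, theta)
        for m in range(n):
            F[m] = f_of_index(m, m * h, ys[m])
            # convolution: weight w[m-j] multiplies f_j
            ys[m + 1] = y0 + c * (w[: m + 1][::-1] @ F[: m + 1])
    else:
        for m in range(n):
            F[m] = f_of_index(m, m * h, ys[m])
            ys[m + 1] = ys[m] + c * F[m]
    return ys


def _negativity_warnings(ys: np.ndarray, tol: float) -> tuple[str, ...]:
    low = ys.min()
    if low < -tol:
        return (
            f"state left the non-negative region: min component {low:.6g} "
            f"(tolerance {tol:.3g}); the scheme, not the model, is the cause",
        )
    return ()


def solve_caputo(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0,
    order: FractionalOrder | float,
    settings: SolverSettings,
) -> Trajectory:
    """Integrate a Caputo fractional system on a fixed grid.

    ``rhs(t, y)`` is the Caputo right-hand side.  The default
    ``caputo_rectangle`` scheme carries the full memory convolution; the
    ``caputo_memoryless`` scheme is the one-step variant
    y_{n+1} = y_n + h^theta/Gamma(theta+1) f(t_n, y_n).  Negative
    excursions are recorded as trajectory warnings, never raised.
    """
    theta = _as_theta(order)
    if settings.scheme not in ("caputo_rectangle", "caputo_memoryless"):
        raise DomainError(
            f"solve_caputo requires a Caputo scheme, got {settings.scheme!r}"
        )
    y = _as_y0(y0)
    n = settings.n_steps
    ys = caputo_step_array(
        lambda j, t, yj: np.asarray(rhs(t, yj), dtype=float),
        y,
        theta,
        settings.step,
        n,
        memory=settings.scheme == "caputo_rectangle",
    )
    if ys.shape[1] != 6:
        # scalar / non-model systems: pad into the 6-column container is
        # wrong; return a bare grid container instead.
        return _BareTrajectory(settings.grid(), ys, _negativity_warnings(ys, settings.negativity_tolerance))
    return Trajectory(
        settings.grid(), ys, warnings=_negativity_warnings(ys, settings.negativity_tolerance)
    )


class _BareTrajectory:
    """Minimal grid/values container for non-6-dimensional systems."""

    def __init__(self, times: np.ndarray, states: np.ndarray, warnings: tuple[str, ...] = ()):
        self.times = times
        self.states = states
        self.warnings = warnings

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()


def solve_classical(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0,
    settings: SolverSettings,
) -> Trajectory:
    """Fixed-step classical RK4 integration (the theta = 1 reference)."""
    if settings.scheme != "classical_rk":
        raise DomainError(
            f"solve_classical requires scheme='classical_rk', got {settings.scheme!r}"
        )
    y = _as_y0(y0)
    h = settings.step
    n = settings.n_steps
    ys = np.empty((n + 1, y.size))
    ys[0] = y
    for m in range(n):
        t = m * h
        ym = ys[m]
        k1 = np.asarray(rhs(t, ym), dtype=float)
        k2 = np.asarray(rhs(t + 0.5 * h, ym + 0.5 * h * k1), dtype=float)
        k3 = np.asarray(rhs(t + 0.5 * h, ym + 0.5 * h * k2), dtype=float)
        k4 = np.asarray(rhs(t + h, ym + h * k3), dtype=float)
        ys[m + 1] = ym + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    warns = _negativity_warnings(ys, settings.negativity_tolerance)
    if ys.shape[1] != 6:
        return _BareTrajectory(settings.grid(), ys, warns)
    return Trajectory(settings.grid(), ys, warnings=warns)
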