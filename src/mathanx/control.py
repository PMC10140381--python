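"""Two-control fractional optimal-control problem.

Control c1(t) in [0, 1] is a prevention effort scaling the incidence by
(1 - c1); control c2(t) in [0, 1] is the intensity of treatment, turning
the treatment term gamma^theta * A on in the A and R equations.  The cost

    J(c1, c2) = int_0^T ( U1 E + U2 A + B1/2 c1^2 + B2/2 c2^2 ) dt

penalizes exposed and anxiety-infected head-counts plus quadratic control
effort.  The Hamiltonian, adjoint system and control characterization are
derived consistently from these controlled dynamics and this objective
(derivatives of the standard incidence treat the total N as a function of
the state), and the derivation is enforced by a finite-difference
gradient test in the suite.  Necessary conditions are solved by a
forward-backward sweep: forward Caputo solve of the states, backward
Caputo solve of the adjoints from the transversality condition
lambda_i(T) = 0 (by time reversal, with the same explicit scheme), and a
relaxed, clipped control update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, GridMismatchError
from .model import (
    FractionalOrder,
    ModelParameters,
    StateVector,
    Trajectory,
    _as_theta,
)
from .solvers import SolverSettings, caputo_step_array

__all__ = [
    "ControlProblem",
    "ControlSolution",
    "controlled_rhs",
    "objective",
    "adjoint_rhs",
    "control_characterization",
    "forward_backward_sweep",
    "hamiltonian",
]


@dataclass(frozen=True)
class ControlProblem:
    """Objective weights and horizon of the control problem.

    U1, U2 weight the exposed and infected head-counts; B1, B2 weight the
    quadratic effort of prevention and treatment.  No canonical numeric
    weights or horizon exist for this problem, so the defaults here
    (U1 = U2 = B1 = B2 = 1, T = 10) are package defaults, fully
    configurable (see docs/methods.md).
    """

    U1: float = 1.0
    U2: float = 1.0
    B1: float = 1.0
    B2: float = 1.0
    horizon: float = 10.0
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.U1 < 0 or self.U2 < 0:
            raise DomainError("state-cost weights U1, U2 must be >= 0")
        if self.B1 <= 0 or self.B2 <= 0:
            raise DomainError("effort weights B1, B2 must be > 0")
        if not self.horizon > 0:
            raise DomainError("horizon must be > 0")
        if self.bounds != (0.0, 1.0):
            raise DomainError("controls are defined on [0, 1]")


@dataclass(frozen=True)
class ControlSolution:
    """Output of the forward-backward sweep."""

    controls: np.ndarray  # (n+1, 2)
    adjoints: np.ndarray  # (n+1, 6)
    trajectory: Trajectory
    objective: float
    iterations: int
    converged: bool


def _check_controls(c1: float, c2: float) -> None:
    if not (0.0 <= c1 <= 1.0 and 0.0 <= c2 <= 1.0):
        raise DomainError(f"controls must lie in [0, 1], got ({c1!r}, {c2!r})")


def controlled_rhs_array(
    y: np.ndarray, c1: float, c2: float, p: ModelParameters
) -> np.ndarray:
    """Controlled vector field on a raw 6-array with *powered* parameters."""
    S, P, E, A, Q, R = y
    N = S + P + E + A + Q + R
    if not N > 0:
        raise DomainError(f"total population must be > 0, got N={N!r}")
    lam = p.beta * (A + p.phi * Q) / N
    loss = (1.0 - p.kappa) * p.rho
    return np.array(
        [
            (1.0 - p.epsilon) * p.Delta + p.omega * R + loss * P - ((1.0 - c1) * lam + p.mu) * S,
            p.epsilon * p.Delta - (p.mu + loss) * P,
            (1.0 - c1) * lam * S - (p.mu + p.psi) * E,
            (1.0 - p.sigma) * p.psi * E - (p.mu + p.delta + c2 * p.gamma) * A,
            p.delta * A - p.mu * Q,
            c2 * p.gamma * A + p.sigma * p.psi * E - (p.mu + p.omega) * R,
        ]
    )


def controlled_rhs(
    state: StateVector,
    controls: tuple[float, float],
    params: ModelParameters,
    order: FractionalOrder | float,
) -> np.ndarray:
    """Caputo right-hand side of the controlled system.

    With c1 = 0 and c2 = 0 the incidence is uncontrolled and the
    treatment pathway gamma^theta A is switched off entirely (both in
    A's outflow and R's inflow); c2 = 1 restores the uncontrolled
    treatment term.
    """
    c1, c2 = float(controls[0]), float(controls[1])
    _check_controls(c1, c2)
    return controlled_rhs_array(state.as_array(), c1, c2, params.powered(order))


def objective(
    trajectory: Trajectory,
    controls: np.ndarray,
    problem: ControlProblem,
) -> float:
    """Trapezoidal quadrature of the running cost over the horizon."""
    c = np.asarray(controls, dtype=float)
    if c.shape != (trajectory.times.size, 2):
        raise GridMismatchError(
            f"controls shape {c.shape} does not match grid of "
            f"{trajectory.times.size} points"
        )
    E = trajectory.states[:, 2]
    A = trajectory.states[:, 3]
    integrand = (
        problem.U1 * E
        + problem.U2 * A
        + 0.5 * problem.B1 * c[:, 0] ** 2
        + 0.5 * problem.B2 * c[:, 1] ** 2
    )
    return float(np.trapezoid(integrand, trajectory.times))


def hamiltonian(
    y: np.ndarray,
    adjoints: np.ndarray,
    controls: tuple[float, float],
    params: ModelParameters,
    problem: ControlProblem,
    order: FractionalOrder | float,
) -> float:
    """Pontryagin Hamiltonian: running cost plus adjoint-weighted dynamics."""
    c1, c2 = controls
    p = params.powered(order)
    f = controlled_rhs_array(np.asarray(y, float), c1, c2, p)
    running = (
        problem.U1 * y[2]
        + problem.U2 * y[3]
        + 0.5 * problem.B1 * c1**2
        + 0.5 * problem.B2 * c2**2
    )
    return float(running + np.dot(np.asarray(adjoints, float), f))


def _hamiltonian_state_gradient(
    y: np.ndarray,
    a: np.ndarray,
    c1: float,
    c2: float,
    p: ModelParameters,
    problem: ControlProblem,
) -> np.ndarray:
    """Analytic dH/dx with powered parameters p.

    The incidence lam = beta (A + phi Q)/N depends on every compartment
    through N (quotient rule), so each partial carries a -lam/N term.
    """
    S, P, E, A, Q, R = y
    N = S + P + E + A + Q + R
    lam = p.beta * (A + p.phi * Q) / N
    # d lam / d x for x = S,P,E,A,Q,R
    dlam = np.full(6, -lam / N)
    dlam[3] = (p.beta - lam) / N
    dlam[4] = (p.beta * p.phi - lam) / N
    u = 1.0 - c1
    loss = (1.0 - p.kappa) * p.rho
    m3 = p.mu + loss
    m4 = p.mu + p.psi
    m7 = p.mu + p.omega
    # d(lam*S)/dx = dlam*S + lam * [x == S]
    dlamS = dlam * S
    dlamS[0] += lam
    g = np.zeros(6)
    # contributions of f1 = ... - (u lam + mu) S  and f3 = u lam S - m4 E
    g += (a[2] - a[0]) * u * dlamS
    g[0] += -a[0] * p.mu
    g[1] += a[0] * loss - a[1] * m3
    g[2] += problem.U1 - a[2] * m4 + a[3] * (1.0 - p.sigma) * p.psi + a[5] * p.sigma * p.psi
    g[3] += (
        problem.U2
        - a[3] * (p.mu + p.delta + c2 * p.gamma)
        + a[4] * p.delta
        + a[5] * c2 * p.gamma
    )
    g[4] += -a[4] * p.mu
    g[5] += a[0] * p.omega - a[5] * m7
    return g


def adjoint_rhs(
    state: StateVector | np.ndarray,
    adjoints: np.ndarray,
    controls: tuple[float, float],
    params: ModelParameters,
    problem: ControlProblem,
    order: FractionalOrder | float,
) -> np.ndarray:
    """Adjoint derivatives -dH/dx (forward-time convention).

    Pontryagin's principle gives D^theta lambda_i = -dH/dx_i with the
    terminal (transversality) condition lambda_i(T) = 0.
    """
    y = state.as_array() if isinstance(state, StateVector) else np.asarray(state, float)
    a = np.asarray(adjoints, dtype=float)
    c1, c2 = float(controls[0]), float(controls[1])
    p = params.powered(order)
    return -_hamiltonian_state_gradient(y, a, c1, c2, p, problem)


def control_characterization(
    state: StateVector | np.ndarray,
    adjoints: np.ndarray,
    params: ModelParameters,
    problem: ControlProblem,
    order: FractionalOrder | float,
) -> tuple[float, float]:
    """Stationary controls projected onto [0, 1].

    Setting dH/dc_i = 0 gives the interior candidates

        c1 = (lambda_3 - lambda_1) * lam * S / B1,
        c2 = (lambda_4 - lambda_6) * gamma^theta * A / B2,

    which are clipped to the admissible interval.
    """
    y = state.as_array() if isinstance(state, StateVector) else np.asarray(state, float)
    a = np.asarray(adjoints, dtype=float)
    p = params.powered(order)
    N = y.sum()
    if not N > 0:
        raise DomainError("total population must be > 0")
    lam = p.beta * (y[3] + p.phi * y[4]) / N
    c1 = (a[2] - a[0]) * lam * y[0] / problem.B1
    c2 = (a[3] - a[5]) * p.gamma * y[3] / problem.B2
    return (float(np.clip(c1, 0.0, 1.0)), float(np.clip(c2, 0.0, 1.0)))


def _forward_solve(
    y0: np.ndarray,
    controls: np.ndarray,
    p: ModelParameters,
    theta: float,
    h: float,
    n: int,
) -> np.ndarray:
    return caputo_step_array(
        lambda j, t, y: controlled_rhs_array(y, controls[j, 0], controls[j, 1], p),
        y0,
        theta,
        h,
        n,
    )


def _backward_solve(
    states: np.ndarray,
    controls: np.ndarray,
    p: ModelParameters,
    theta: float,
    h: float,
    n: int,
    problem: ControlProblem,
) -> np.ndarray:
    """Solve the adjoint system backward from lambda(T) = 0.

    In reversed time tau = T - t the adjoint equation
    D^theta lambda = -dH/dx becomes D_tau^theta lambda = +dH/dx with a
    zero initial condition, integrated with the same Caputo scheme; the
    state and controls are sampled at the mirrored grid index.
    """

    def rhs(j: int, tau: float, a: np.ndarray) -> np.ndarray:
        k = n - j  # forward-time index of reversed node j
        return _hamiltonian_state_gradient(
            states[k], a, controls[k, 0], controls[k, 1], p, problem
        )

    rev = caputo_step_array(rhs, np.zeros(6), theta, h, n)
    return rev[::-1].copy()  # back to forward time: lambda(T) = 0


def forward_backward_sweep(
    problem: ControlProblem,
    params: ModelParameters,
    order: FractionalOrder | float,
    y0: StateVector,
    settings: SolverSettings,
    tol: float = 1e-4,
    max_iter: int = 200,
    relaxation: float = 0.5,
) -> ControlSolution:
    """Iterate forward state / backward adjoint solves to the optimum.

    Controls are initialized at zero, updated through the projected
    characterization with convex relaxation
    c <- (1 - w) c_old + w c_new, and iteration stops when
    max |Delta c| < tol or after ``max_iter`` sweeps (then
    ``converged=False`` is returned rather than raising).
    """
    if not (0.0 < relaxation <= 1.0):
        raise DomainError(f"relaxation must lie in (0, 1], got {relaxation!r}")
    if not tol > 0:
        raise DomainError(f"tol must be > 0, got {tol!r}")
    theta = _as_theta(order)
    p = params.powered(theta)
    h = settings.step
    n = int(round(problem.horizon / h))
    y_init = y0.as_array()
    controls = np.zeros((n + 1, 2))
    states = _forward_solve(y_init, controls, p, theta, h, n)
    adjoints = np.zeros((n + 1, 6))
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        states = _forward_solve(y_init, controls, p, theta, h, n)
        adjoints = _backward_solve(states, controls, p, theta, h, n, problem)
        new = np.empty_like(controls)
        for j in range(n + 1):
            new[j] = control_characterization(
                states[j], adjoints[j], params, problem, theta
            )
        updated = np.clip((1.0 - relaxation) * controls + relaxation * new, 0.0, 1.0)
        delta = float(np.max(np.abs(updated - controls)))
        controls = updated
        if delta < tol:
            converged = True
            break
    states = _forward_solve(y_init, controls, p, theta, h, n)
    times = h * np.arange(n + 1, dtype=float)
    traj = Trajectory(times, states, controls=controls, adjoints=adjoints)
    J = objective(traj, controls, problem)
    return ControlSolution(
        controls=controls,
        adjoints=adjoints,
        trajectory=traj,
        objective=J,
        iterations=iterations,
        converged=converged,
    )
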