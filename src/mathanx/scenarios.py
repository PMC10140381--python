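"""Scenario fixtures, configuration round-trips and CSV output.

The baseline scenario carries the published simulation parameter set
(Delta=100, mu=0.5, psi=0.04, epsilon=0.4, kappa=0.8, gamma=0.01,
omega=0.03, rho=0.2, delta=0.3, sigma=0.04, phi=1.3, beta=1.4).  No
initial conditions are published alongside that set, so
the fixture initial state (S=150, P=30, E=10, A=5, Q=3, R=2) is a
documented repository choice whose total equals the demographic carrying
total Delta/mu = 200.  Randomized scenarios drive the property tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import DomainError
from .model import FractionalOrder, ModelParameters, StateVector, Trajectory
from .solvers import SolverSettings

__all__ = [
    "Scenario",
    "baseline_scenario",
    "random_scenario",
    "DEFAULT_RANGES",
    "load_scenario",
    "save_scenario",
    "trajectory_to_csv",
]

#: Sampling intervals for randomized scenarios.  Rates are kept within
#: the same order of magnitude as the baseline set; fractions stay away
#: from the degenerate endpoints.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "Delta": (50.0, 150.0),
    "mu": (0.1, 1.0),
    "psi": (0.01, 0.5),
    "epsilon": (0.05, 0.9),
    "kappa": (0.1, 0.95),
    "gamma": (0.005, 0.5),
    "omega": (0.01, 0.3),
    "rho": (0.05, 0.5),
    "delta": (0.05, 0.5),
    "sigma": (0.01, 0.5),
    "phi": (0.5, 2.0),
    "beta": (0.1, 5.0),
}


@dataclass(frozen=True)
class Scenario:
    """A complete, reproducible simulation setup."""

    params: ModelParameters
    theta: FractionalOrder
    y0: StateVector
    solver: SolverSettings
    label: str = ""

    def __post_init__(self) -> None:
        if not self.y0.N > 0:
            raise DomainError("initial state must have positive total")

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "theta": float(self.theta.theta),
            "y0": self.y0.to_dict(),
            "solver": {
                "step": float(self.solver.step),
                "horizon": float(self.solver.horizon),
                "scheme": self.solver.scheme,
                "negativity_tolerance": float(self.solver.negativity_tolerance),
            },
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            params=ModelParameters.from_dict(d["params"]),
            theta=FractionalOrder(float(d["theta"])),
            y0=StateVector.from_dict(d["y0"]),
            solver=SolverSettings(**d.get("solver", {})),
            label=str(d.get("label", "")),
        )


def baseline_scenario(theta: float = 1.0) -> Scenario:
    """The published baseline parameter set with the fixture initial state."""
    return Scenario(
        params=ModelParameters(
            Delta=100.0,
            mu=0.5,
            psi=0.04,
            epsilon=0.4,
            kappa=0.8,
            gamma=0.01,
            omega=0.03,
            rho=0.2,
            delta=0.3,
            sigma=0.04,
            phi=1.3,
            beta=1.4,
        ),
        theta=FractionalOrder(theta),
        y0=StateVector(S=150.0, P=30.0, E=10.0, A=5.0, Q=3.0, R=2.0),
        solver=SolverSettings(step=0.01, horizon=50.0),
        label="baseline",
    )


def random_scenario(
    seed: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    theta: float = 1.0,
) -> Scenario:
    """Deterministically sample a valid scenario from per-parameter ranges.

    Parameters are uniform over their intervals; the initial state has
    positive components (Dirichlet split) summing to Delta/mu.  The same
    seed always yields the same scenario.
    """
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    for name, (lo, hi) in ranges.items():
        if name not in DEFAULT_RANGES:
            raise DomainError(f"unknown parameter {name!r} in ranges")
        if not (0 <= lo < hi):
            raise DomainError(f"invalid range for {name!r}: ({lo}, {hi})")
        if name in ("epsilon", "kappa", "sigma") and hi > 1:
            raise DomainError(f"range for fraction {name!r} must stay within [0, 1]")
    rng = np.random.default_rng(seed)
    draws = {
        name: float(rng.uniform(lo, hi)) for name, (lo, hi) in sorted(ranges.items())
    }
    params = ModelParameters(**draws)
    total = params.Delta / params.mu
    split = rng.dirichlet(np.ones(6)) * total
    y0 = StateVector(*np.maximum(split, 1e-9))
    return Scenario(
        params=params,
        theta=FractionalOrder(theta),
        y0=y0,
        solver=SolverSettings(step=0.01, horizon=50.0),
        label=f"random-{seed}",
    )


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario config as YAML (.yaml/.yml) or JSON (.json)."""
    path = Path(path)
    d = scenario.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    elif path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True))
    else:
        raise DomainError(f"unsupported config extension {path.suffix!r}")


def load_scenario(path: str | Path) -> Scenario:
    """Read a scenario config (YAML or JSON)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    elif path.suffix == ".json":
        d = json.loads(text)
    else:
        raise DomainError(f"unsupported config extension {path.suffix!r}")
    if not isinstance(d, dict):
        raise DomainError(f"malformed config in {path}")
    try:
        return Scenario.from_dict(d)
    except (KeyError, TypeError) as exc:
        raise DomainError(f"malformed config in {path}: {exc}") from exc


def trajectory_to_csv(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV with header t,S,P,E,A,Q,R,N.

    Floats are written repr-faithfully (shortest round-trip), so the file
    reloads bit-for-bit.
    """
    trajectory.to_frame().to_csv(path, index=False)
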