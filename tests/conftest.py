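import numpy as np
import pytest

from mathanx import ModelParameters, baseline_scenario, random_scenario


@pytest.fixture(scope="session")
def baseline():
    return baseline_scenario()


@pytest.fixture(scope="session")
def baseline_params(baseline):
    return baseline.params


@pytest.fixture(scope="session")
def high_beta_params(baseline_params):
    """Baseline with beta raised to 15, putting R_eff above one."""
    return ModelParameters.from_dict({**baseline_params.to_dict(), "beta": 15.0})


def steady_state_for_lambda(lam, p):
    """Independent steady-state solve: fix the force of infection lam and
    solve the six linear balance equations with numpy.  Used as an oracle
    for the package's closed-form endemic reconstruction."""
    loss = (1.0 - p.kappa) * p.rho
    M = np.array(
        [
            [-(lam + p.mu), loss, 0.0, 0.0, 0.0, p.omega],
            [0.0, -(p.mu + loss), 0.0, 0.0, 0.0, 0.0],
            [lam, 0.0, -(p.mu + p.psi), 0.0, 0.0, 0.0],
            [0.0, 0.0, (1.0 - p.sigma) * p.psi, -(p.mu + p.delta + p.gamma), 0.0, 0.0],
            [0.0, 0.0, 0.0, p.delta, -p.mu, 0.0],
            [0.0, 0.0, p.sigma * p.psi, p.gamma, 0.0, -(p.mu + p.omega)],
        ]
    )
    b = np.array([-(1.0 - p.epsilon) * p.Delta, -p.epsilon * p.Delta, 0, 0, 0, 0.0])
    return np.linalg.solve(M, b)


def fixed_point_lambda(p, lam0=1.0, iters=500):
    """Oracle: iterate lam <- beta (A + phi Q)/N on the linear-solve map."""
    lam = lam0
    for _ in range(iters):
        y = steady_state_for_lambda(lam, p)
        new = p.beta * (y[3] + p.phi * y[4]) / y.sum()
        if abs(new - lam) < 1e-14 * max(1.0, abs(lam)):
            return new
        lam = 0.5 * lam + 0.5 * new
    return lam


@pytest.fixture(scope="session")
def endemic_oracle():
    return fixed_point_lambda


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def scenarios_with_reff_above_one(count, seed0=100):
    """Random scenarios rescaled so the reproduction number exceeds one."""
    from mathanx import critical_parameter

    out = []
    seed = seed0
    while len(out) < count:
        sc = random_scenario(seed)
        seed += 1
        try:
            beta_star = critical_parameter(sc.params, 1.0, "beta", (1e-4, 1e4))
        except Exception:
            continue
        factor = 1.5 + (seed % 7) * 0.5
        params = ModelParameters.from_dict(
            {**sc.params.to_dict(), "beta": beta_star * factor}
        )
        out.append(params)
    return out
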