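import numpy as np
import pytest

from mathanx import (
    ControlProblem,
    DomainError,
    GridMismatchError,
    SolverSettings,
    StateVector,
    Trajectory,
    adjoint_rhs,
    control_characterization,
    controlled_rhs,
    forward_backward_sweep,
    fractional_rhs,
    objective,
)
from mathanx.control import _forward_solve, hamiltonian

STATE = StateVector(S=100, P=40, E=20, A=15, Q=8, R=6)


def uncontrolled_trajectory(scenario, theta, horizon, step=0.01):
    p = scenario.params.powered(theta)
    n = int(round(horizon / step))
    zeros = np.zeros((n + 1, 2))
    ys = _forward_solve(scenario.y0.as_array(), zeros, p, theta, step, n)
    return Trajectory(step * np.arange(n + 1.0), ys), zeros


class TestControlledRhs:
    def test_full_prevention_stops_exposure_inflow(self, baseline_params):
        out = controlled_rhs(STATE, (1.0, 0.0), baseline_params, 1.0)
        # E equation: no incidence inflow, only -(mu+psi) E outflow
        assert out[2] == pytest.approx(-(0.5 + 0.04) * STATE.E, rel=1e-12)

    def test_no_treatment_removes_recovery_pathway(self, baseline_params):
        out = controlled_rhs(STATE, (0.0, 0.0), baseline_params, 1.0)
        # A outflow coefficient is mu + delta only; R loses gamma A inflow
        expected_A = 0.96 * 0.04 * STATE.E - (0.5 + 0.3) * STATE.A
        expected_R = 0.04 * 0.04 * STATE.E - (0.5 + 0.03) * STATE.R
        assert out[3] == pytest.approx(expected_A, rel=1e-12)
        assert out[5] == pytest.approx(expected_R, rel=1e-12)

    def test_full_treatment_recovers_uncontrolled_structure(self, baseline_params):
        out = controlled_rhs(STATE, (0.0, 1.0), baseline_params, 1.0)
        base = fractional_rhs(STATE, baseline_params, 1.0)
        np.testing.assert_allclose(out, base, rtol=1e-12)

    def test_controls_outside_unit_interval_rejected(self, baseline_params):
        with pytest.raises(DomainError):
            controlled_rhs(STATE, (1.2, 0.0), baseline_params, 1.0)
        with pytest.raises(DomainError):
            controlled_rhs(STATE, (0.0, -0.1), baseline_params, 1.0)


class TestObjective:
    def test_zero_cost_for_empty_infection_and_idle_controls(self):
        times = np.linspace(0, 5, 51)
        states = np.zeros((51, 6))
        states[:, 0] = 10.0
        traj = Trajectory(times, states)
        prob = ControlProblem(horizon=5.0)
        assert objective(traj, np.zeros((51, 2)), prob) == 0.0

    def test_constant_integrand(self):
        times = np.linspace(0, 5, 501)
        states = np.zeros((501, 6))
        states[:, 0] = 1.0
        states[:, 2] = 1.0  # E = 1
        traj = Trajectory(times, states)
        prob = ControlProblem(U1=2.0, U2=1.0, horizon=5.0)
        assert objective(traj, np.zeros((501, 2)), prob) == pytest.approx(10.0, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        times = np.linspace(0, 1, 11)
        traj = Trajectory(times, np.ones((11, 6)))
        with pytest.raises(GridMismatchError):
            objective(traj, np.zeros((10, 2)), ControlProblem(horizon=1.0))


class TestAdjointSystem:
    def test_zero_adjoints_zero_weights_give_zero_vector(self, baseline_params):
        prob = ControlProblem(U1=0.0, U2=0.0)
        s = StateVector(S=100, P=40, E=0, A=0, Q=8, R=6)
        out = adjoint_rhs(s, np.zeros(6), (0.2, 0.3), baseline_params, prob, 0.8)
        np.testing.assert_allclose(out, np.zeros(6), atol=1e-14)

    def test_exposed_cost_enters_exposed_adjoint(self, baseline_params):
        prob = ControlProblem(U1=3.5, U2=0.0)
        s = StateVector(S=100, P=40, E=1, A=0, Q=0, R=0)
        out = adjoint_rhs(s, np.zeros(6), (0.0, 0.0), baseline_params, prob, 1.0)
        assert out[2] == pytest.approx(-3.5, rel=1e-12)

    @pytest.mark.parametrize("theta", [0.6, 1.0])
    def test_matches_finite_difference_hamiltonian_gradient(
        self, baseline_params, theta
    ):
        prob = ControlProblem(U1=1.0, U2=2.0, B1=0.5, B2=4.0)
        rng = np.random.default_rng(7)
        y = np.array([120.0, 30.0, 25.0, 12.0, 9.0, 4.0])
        a = rng.normal(size=6)
        c = (0.35, 0.6)
        g = -adjoint_rhs(y, a, c, baseline_params, prob, theta)
        fd = np.empty(6)
        for i in range(6):
            e = np.zeros(6)
            e[i] = 1e-5
            fd[i] = (
                hamiltonian(y + e, a, c, baseline_params, prob, theta)
                - hamiltonian(y - e, a, c, baseline_params, prob, theta)
            ) / 2e-5
        np.testing.assert_allclose(g, fd, rtol=1e-6, atol=1e-8)


class TestControlCharacterization:
    def test_equal_adjoints_give_idle_controls(self, baseline_params):
        prob = ControlProblem()
        c1, c2 = control_characterization(
            STATE, np.full(6, 2.7), baseline_params, prob, 1.0
        )
        assert (c1, c2) == (0.0, 0.0)

    def test_large_adjoint_gap_saturates(self, baseline_params):
        prob = ControlProblem()
        a = np.zeros(6)
        a[2] = 1e9  # lambda_3 >> lambda_1
        c1, _ = control_characterization(STATE, a, baseline_params, prob, 1.0)
        assert c1 == 1.0

    def test_interior_value_minimizes_hamiltonian_scan(self, baseline_params):
        prob = ControlProblem(B1=100.0, B2=5.0)
        rng = np.random.default_rng(3)
        a = rng.normal(scale=0.5, size=6)
        a[2] = 2.0  # make the c1 candidate interior and positive
        c1, c2 = control_characterization(STATE, a, baseline_params, prob, 1.0)
        grid = np.linspace(0, 1, 2001)
        h_vals = [
            hamiltonian(STATE.as_array(), a, (g, c2), baseline_params, prob, 1.0)
            for g in grid
        ]
        assert 0 < c1 < 1
        assert c1 == pytest.approx(grid[int(np.argmin(h_vals))], abs=1e-3)


class TestForwardBackwardSweep:
    @pytest.fixture(scope="class")
    def sweep(self, baseline):
        prob = ControlProblem(horizon=5.0)
        return (
            prob,
            forward_backward_sweep(
                prob,
                baseline.params,
                1.0,
                baseline.y0,
                SolverSettings(step=0.02, horizon=5.0),
            ),
        )

    def test_converges_with_feasible_controls(self, sweep):
        _, sol = sweep
        assert sol.converged
        assert sol.iterations <= 200
        assert np.all(sol.controls >= 0) and np.all(sol.controls <= 1)

    def test_transversality(self, sweep):
        _, sol = sweep
        np.testing.assert_array_equal(sol.adjoints[-1], np.zeros(6))

    def test_improves_on_constant_policies(self, sweep, baseline):
        prob, sol = sweep
        for const in (0.0, 1.0):
            traj, _ = uncontrolled_trajectory(baseline, 1.0, 5.0, 0.02)
            n = traj.times.size
            c = np.full((n, 2), const)
            p = baseline.params.powered(1.0)
            ys = _forward_solve(baseline.y0.as_array(), c, p, 1.0, 0.02, n - 1)
            J_const = objective(Trajectory(traj.times, ys), c, prob)
            assert sol.objective <= J_const + 1e-9

    def test_controlled_burden_pointwise_below_uncontrolled(self, sweep, baseline):
        _, sol = sweep
        traj0, _ = uncontrolled_trajectory(baseline, 1.0, 5.0, 0.02)
        assert np.all(sol.trajectory.states[:, 2] <= traj0.states[:, 2] + 1e-9)
        assert np.all(sol.trajectory.states[:, 3] <= traj0.states[:, 3] + 1e-9)

    def test_prohibitive_effort_cost_idles_controls(self, baseline):
        prob = ControlProblem(B1=1e9, B2=1e9, horizon=2.0)
        sol = forward_backward_sweep(
            prob,
            baseline.params,
            1.0,
            baseline.y0,
            SolverSettings(step=0.02, horizon=2.0),
        )
        assert sol.converged
        assert np.max(sol.controls) < 1e-5
        traj0, zeros = uncontrolled_trajectory(baseline, 1.0, 2.0, 0.02)
        J0 = objective(traj0, zeros, prob)
        assert sol.objective == pytest.approx(J0, rel=1e-4)

    def test_fractional_order_sweep_converges(self, baseline):
        prob = ControlProblem(horizon=3.0)
        sol = forward_backward_sweep(
            prob,
            baseline.params,
            0.5,
            baseline.y0,
            SolverSettings(step=0.02, horizon=3.0),
        )
        assert sol.converged
        np.testing.assert_array_equal(sol.adjoints[-1], np.zeros(6))
        assert np.all(sol.controls >= 0) and np.all(sol.controls <= 1)

    def test_invalid_relaxation_rejected(self, baseline):
        with pytest.raises(DomainError):
            forward_backward_sweep(
                ControlProblem(horizon=1.0),
                baseline.params,
                1.0,
                baseline.y0,
                SolverSettings(step=0.1, horizon=1.0),
                relaxation=0.0,
            )
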