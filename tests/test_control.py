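"""Controlled dynamics, Pontryagin conditions and the sweep solver."""

import numpy as np
import pytest

from drugdyn.control import (
    AdjointState,
    CostWeights,
    OCProblem,
    adjoint_rhs,
    controlled_rhs,
    fbsm_solve,
    hamiltonian,
    objective,
    optimal_controls_pointwise,
    reference_problem,
    running_cost,
    simulate_controlled,
)
from drugdyn.model import StateVector, ode_rhs, sample_parameters

REF_WEIGHTS = CostWeights(A=5e-7, B=3e-7)


def random_state(rng):
    raw = rng.uniform(0, 1, 5)
    return StateVector.from_array(raw / raw.sum() * rng.uniform(0.3, 1.0))


class TestControlledField:
    def test_reduces_to_uncontrolled_at_baseline_detection_effort(self, rng):
        # v multiplies the detection rates, so unit effort (and no social
        # blocking) recovers the uncontrolled vector field exactly
        for _ in range(20):
            params = sample_parameters(rng)
            state = random_state(rng)
            diff = controlled_rhs(0.0, state, 0.0, 1.0, params) - ode_rhs(
                0.0, state, params
            )
            assert np.max(np.abs(diff)) < 1e-15  # association roundoff only

    def test_full_social_blocking_stops_initiation(self, baseline, mixed_state):
        rhs = controlled_rhs(0.0, mixed_state, 1.0, 0.0, baseline)
        p, s = baseline, mixed_state
        assert rhs[0] == pytest.approx(p.mu - p.mu * s.S, abs=1e-15)
        # with v=0 the detection term gamma*v vanishes from the I outflow
        outflow = p.alpha + p.sigma + p.mu + p.psi
        assert rhs[1] == pytest.approx(-outflow * s.I, abs=1e-15)

    def test_full_detection_effort_by_hand(self, baseline, mixed_state):
        # with v=1: dR/dt = gamma*I + rho*Ia + epsilon*M = 0.0055
        rhs = controlled_rhs(0.0, mixed_state, 0.0, 1.0, baseline)
        assert rhs[4] == pytest.approx(0.0055, abs=1e-15)


class TestRunningCost:
    def test_zero_when_idle_and_drug_free(self):
        s = StateVector(1, 0, 0, 0, 0)
        assert running_cost(s, 0.0, 0.0, REF_WEIGHTS) == 0.0

    def test_literal_and_symmetric_integrands_by_hand(self, mixed_state):
        literal = running_cost(mixed_state, 0.95, 0.95, REF_WEIGHTS)
        assert literal == pytest.approx(
            0.03 + 5e-7 * 0.9025 + 1.5e-7 * 0.9025, rel=1e-14
        )
        symmetric = running_cost(
            mixed_state, 0.95, 0.95, CostWeights(5e-7, 3e-7, form="symmetric")
        )
        assert symmetric == pytest.approx(
            0.03 + 2.5e-7 * 0.9025 + 1.5e-7 * 0.9025, rel=1e-14
        )


class TestAdjointSystem:
    def test_terminal_costate_rows_by_hand(self, baseline, mixed_state):
        zero = np.zeros(5)
        rhs = adjoint_rhs(0.0, zero, mixed_state, 0.3, 0.4, baseline, REF_WEIGHTS)
        assert rhs[0] == 0.0        # S row: only costate couplings
        assert rhs[1] == -1.0       # I row: running-cost gradient survives
        assert rhs[2] == -1.0       # Ia row likewise
        rhs_r = adjoint_rhs(
            0.0, np.array([0, 0, 0, 0, 1.0]), mixed_state, 0.0, 0.0,
            baseline, REF_WEIGHTS,
        )
        assert rhs_r[4] == pytest.approx(baseline.mu + baseline.omega, abs=1e-15)

    def test_matches_negative_state_gradient_of_hamiltonian(self, baseline, rng):
        # dp/dt must equal -dH/dx at random interior points
        for _ in range(10):
            state = random_state(rng)
            adj = rng.normal(0, 3, 5)
            u, v = rng.uniform(0, 0.95, 2)
            got = adjoint_rhs(0.0, adj, state, u, v, baseline, REF_WEIGHTS)
            y0 = state.as_array()
            h = 1e-7
            for j in range(5):
                step = np.zeros(5)
                step[j] = h
                dh = (
                    hamiltonian(
                        StateVector.from_array(y0 + step), adj, u, v,
                        baseline, REF_WEIGHTS,
                    )
                    - hamiltonian(
                        StateVector.from_array(y0 - step), adj, u, v,
                        baseline, REF_WEIGHTS,
                    )
                ) / (2 * h)
                assert got[j] == pytest.approx(-dh, abs=1e-6)

    def test_transversality_enforced_by_container(self, baseline):
        times = np.linspace(0, 1, 3)
        bad = np.ones((3, 5))
        with pytest.raises(ValueError, match="vanish"):
            AdjointState(times, bad)


class TestPointwiseControls:
    def test_zero_costates_give_zero_controls(self, baseline, mixed_state):
        u, v = optimal_controls_pointwise(
            mixed_state, np.zeros(5), baseline, REF_WEIGHTS
        )
        assert (u, v) == (0.0, 0.0)

    def test_costly_initiation_saturates_u(self, baseline, mixed_state):
        # p_I = 1: every averted initiation is worth one unit of future cost,
        # so with A ~ 1e-7 the social-influence control saturates
        adj = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
        u, v = optimal_controls_pointwise(mixed_state, adj, baseline, REF_WEIGHTS)
        assert u == 0.95

    def test_detected_costate_alone_pushes_v_to_zero(self, baseline, mixed_state):
        state = StateVector(0.9, 0.05, 0.02, 0.01, 0.0)
        adj = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        _, v = optimal_controls_pointwise(state, adj, baseline, REF_WEIGHTS)
        assert v == 0.0

    def test_returned_point_minimizes_hamiltonian_over_box(self, baseline, rng):
        grid = np.linspace(0.0, 0.95, 11)
        for _ in range(10):
            state = random_state(rng)
            adj = rng.normal(0, 5, 5)
            u, v = optimal_controls_pointwise(state, adj, baseline, REF_WEIGHTS)
            h_star = hamiltonian(state, adj, u, v, baseline, REF_WEIGHTS)
            h_grid = min(
                hamiltonian(state, adj, a, b, baseline, REF_WEIGHTS)
                for a in grid
                for b in grid
            )
            assert h_star <= h_grid + 1e-12


class TestObjective:
    def test_zero_on_drug_free_idle_path(self):
        times = np.linspace(0, 10, 11)
        states = np.tile([1.0, 0, 0, 0, 0], (11, 1))
        zeros = np.zeros(11)
        assert objective(times, states, zeros, zeros, REF_WEIGHTS) == 0.0

    def test_constant_state_hand_value(self):
        times = np.linspace(0, 10, 101)
        states = np.tile([0.97, 0.02, 0.01, 0, 0], (101, 1))
        zeros = np.zeros(101)
        assert objective(times, states, zeros, zeros, REF_WEIGHTS) == pytest.approx(
            0.3, rel=1e-12
        )

    def test_grid_refinement_changes_little_on_smooth_paths(self, baseline):
        init = StateVector(0.97, 0.02, 0.01, 0, 0)
        vals = []
        for n in (501, 1001):
            times = np.linspace(0, 10, n)
            states = simulate_controlled(baseline, init, times, 0.3, 0.3)
            u = np.full(n, 0.3)
            vals.append(objective(times, states, u, u, REF_WEIGHTS))
        assert vals[0] == pytest.approx(vals[1], rel=1e-6)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            objective(
                np.linspace(0, 1, 5),
                np.zeros((5, 5)),
                np.zeros(4),
                np.zeros(5),
                REF_WEIGHTS,
            )


class TestForwardSweep:
    def test_rk4_forward_matches_naive_reimplementation(self, baseline):
        # independent oracle: an explicit numpy RK4 written from scratch
        times = np.linspace(0.0, 1.0, 3)
        u = np.array([0.2, 0.5, 0.8])
        v = np.array([0.1, 0.3, 0.6])
        init = StateVector(0.97, 0.02, 0.01, 0.0, 0.0)
        got = simulate_controlled(baseline, init, times, u, v)

        def f(y, uu, vv):
            return controlled_rhs(0.0, StateVector.from_array(y), uu, vv, baseline)

        y = init.as_array()
        expected = [y]
        for i in range(2):
            h = times[i + 1] - times[i]
            um, vm = (u[i] + u[i + 1]) / 2, (v[i] + v[i + 1]) / 2
            k1 = f(y, u[i], v[i])
            k2 = f(y + h / 2 * k1, um, vm)
            k3 = f(y + h / 2 * k2, um, vm)
            k4 = f(y + h * k3, u[i + 1], v[i + 1])
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            expected.append(y)
        assert np.allclose(got, np.array(expected), atol=1e-15)


class TestFBSM:
    def test_prohibitive_control_cost_means_no_control(self, baseline):
        problem = OCProblem(
            params=baseline,
            T=5.0,
            weights=CostWeights(A=1e6, B=1e6),
            n_nodes=501,
        )
        solution = fbsm_solve(problem)
        assert solution.converged
        assert solution.u.max() < 1e-6
        assert solution.v.max() < 1e-6
        times = solution.times
        idle = simulate_controlled(
            baseline, problem.initial, times, 0.0, 0.0
        )
        j_idle = objective(
            times, idle, np.zeros_like(times), np.zeros_like(times), problem.weights
        )
        assert solution.J == pytest.approx(j_idle, rel=1e-6)

    def test_reference_scenario_structure(self, reference_solution):
        sol = reference_solution
        assert sol.converged
        # controls saturate over most of the horizon, then drop to zero at T
        assert np.mean(sol.u > 0.9) > 0.9
        assert np.mean(sol.v > 0.9) > 0.9
        assert sol.u[-1] == 0.0 and sol.v[-1] == 0.0
        assert np.all(sol.adjoints[-1] == 0.0)
        assert sol.u.min() >= 0 and sol.u.max() <= 0.95

    def test_optimal_path_suppresses_users_below_uncontrolled(
        self, baseline, reference_solution
    ):
        sol = reference_solution
        idle = simulate_controlled(
            baseline, sol.problem.initial, sol.times, 0.0, 0.0
        )
        assert np.all(sol.states[1:, 1] < idle[1:, 1])
        assert np.all(sol.states[1:, 2] < idle[1:, 2])

    def test_cheaper_control_never_reduces_suppression(self, baseline):
        # 10x cheaper control must achieve at least as small an active-user
        # integral (coarser grid keeps this affordable)
        costs = []
        for scale in (1.0, 0.1):
            problem = reference_problem(
                baseline,
                weights=CostWeights(A=5e-7 * scale, B=3e-7 * scale),
                n_nodes=1001,
            )
            sol = fbsm_solve(problem)
            state_cost = float(
                np.trapezoid(sol.states[:, 1] + sol.states[:, 2], sol.times)
            )
            costs.append(state_cost)
        assert costs[1] <= costs[0] + 1e-12

    def test_non_convergence_reports_history(self, baseline):
        problem = OCProblem(
            params=baseline, T=20.0, n_nodes=501, max_iter=2
        )
        sol = fbsm_solve(problem)
        assert not sol.converged
        assert len(sol.j_history) == 2

    def test_solution_csv_round_trip(self, tmp_path, reference_solution):
        import pandas as pd

        path = tmp_path / "solution.csv"
        reference_solution.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns)[:8] == ["t", "S", "I", "Ia", "M", "R", "u", "v"]
        assert len(frame) == reference_solution.times.size
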