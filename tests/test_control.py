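"""Pontryagin machinery: adjoints, FBSM, secant shooting, MED."""

import numpy as np
import pytest

from dosewindow import PatientParameters, adjoint_rhs, control_update
from dosewindow.control import (ControlProblem, ControlSolverError,
                                afbsm_fixed_endpoint, b_sweep, fbsm,
                                med_from_solution)
from dosewindow.model import simulate


@pytest.fixture(scope="module")
def p2(records=None):
    from dosewindow import load_reference_patients
    return {r.patient_id: r for r in load_reference_patients()}[2]


@pytest.fixture(scope="module")
def contained(p2):
    """The containment solution at the literature weight B=691.9."""
    problem = ControlProblem(params=p2.params, B=691.9, k_tol=p2.k0,
                             initial=(0.99 * p2.k0, 0.01 * p2.k0),
                             T=1460.0)
    return problem, afbsm_fixed_endpoint(problem)


class TestAdjointRhs:
    def test_origin_with_zero_adjoints(self, p2):
        dl1, dl2 = adjoint_rhs((0.0, 0.0), (0.0, 0.0), 0.5, p2.params)
        assert (dl1, dl2) == (-1.0, -1.0)

    def test_matches_symbolic_hamiltonian_gradient(self, p2):
        sympy = pytest.importorskip("sympy")
        S, R, l1, l2, u, B = sympy.symbols("S R l1 l2 u B", real=True)
        r, K, delta, c = [sympy.Float(v) for v in p2.params.as_array()]
        H = (S + R + B * u ** 2 / 2
             + l1 * (r * (1 - (S + R) / K) * S - u * delta * S)
             + l2 * r * (1 - (c * S + R) / K) * R)
        dl1_sym = sympy.lambdify((S, R, l1, l2, u, B),
                                 -sympy.diff(H, S))
        dl2_sym = sympy.lambdify((S, R, l1, l2, u, B),
                                 -sympy.diff(H, R))
        rng = np.random.default_rng(3)
        for _ in range(100):
            s, rr = rng.uniform(0, 600, 2)
            a1, a2 = rng.uniform(-50, 50, 2)
            uu = rng.uniform(0, 1)
            got = adjoint_rhs((s, rr), (a1, a2), uu, p2.params)
            want = (dl1_sym(s, rr, a1, a2, uu, 1.0),
                    dl2_sym(s, rr, a1, a2, uu, 1.0))
            assert got[0] == pytest.approx(want[0], abs=1e-10)
            assert got[1] == pytest.approx(want[1], abs=1e-10)

    def test_second_adjoint_independent_of_dose(self, p2):
        state, adj = (300.0, 80.0), (5.0, -2.0)
        _, dl2_a = adjoint_rhs(state, adj, 0.1, p2.params)
        _, dl2_b = adjoint_rhs(state, adj, 0.9, p2.params)
        assert dl2_a == dl2_b


class TestControlUpdate:
    def test_nonpositive_adjoint_gives_zero_dose(self):
        assert control_update(100.0, -3.0, 500.0, 0.1) == 0.0

    def test_saturates_at_mtd(self):
        assert control_update(1e5, 10.0, 1.0, 0.1) == 1.0

    def test_interior_stationarity(self):
        # dH/du = B u - delta S lambda1 = 0 at the unclamped value
        B, delta, S, l1 = 500.0, 0.1, 300.0, 5.0
        u = control_update(S, l1, B, delta)
        assert 0.0 < u < 1.0
        assert B * u - delta * S * l1 == pytest.approx(0.0, abs=1e-12)


class TestFBSM:
    def test_huge_weight_suppresses_dosing(self, p2):
        problem = ControlProblem(params=p2.params, B=1e9, k_tol=p2.k0,
                                 initial=(0.99 * p2.k0, 0.01 * p2.k0),
                                 T=400.0)
        sol = fbsm(problem, lambda1_T=1.0)
        assert sol.converged
        assert sol.u_star.max() < 1e-3

    def test_converged_control_is_a_fixed_point(self, contained):
        problem, sol = contained
        reconstructed = control_update(sol.S, sol.lambda1, problem.B,
                                       problem.params.delta)
        assert np.max(np.abs(sol.u_star - reconstructed)) < 1e-6

    def test_independent_reintegration_reproduces_terminal_state(
            self, contained):
        problem, sol = contained
        policy = lambda t, y: np.interp(t, sol.grid, sol.u_star)  # noqa
        traj = simulate(problem.params, policy, problem.initial,
                        problem.T, t_eval=sol.grid[::16])
        assert abs(traj.S[-1] - sol.S[-1]) < 1e-4 * problem.params.K

    def test_transversality_conditions_hold(self, contained):
        _, sol = contained
        assert sol.lambda2[-1] == 0.0
        assert sol.lambda1[-1] == sol.lambda1_T


class TestAFBSM:
    def test_terminal_gap_contract(self, contained):
        problem, sol = contained
        assert sol.terminal_gap < 1e-3 * problem.k_tol

    def test_containment_profile(self, contained):
        # initial transient then plateau; burden pinned near K_0; the
        # resistant compartment is extinguished
        problem, sol = contained
        k0 = problem.k_tol
        assert np.all(np.abs(sol.total - k0) < 0.05 * k0)
        assert sol.R[-1] < 1e-3 * problem.params.K
        late = sol.u_star[sol.grid > 200.0]
        assert np.std(late[:len(late) // 2]) < 0.01  # plateau is flat

    def test_plateau_matches_window_lower_bound(self, p2, contained):
        _, sol = contained
        nedw_lower = p2.edw().lower_norm
        assert round(sol.plateau(), 2) == round(nedw_lower, 2)

    def test_plateau_inside_normalized_window(self, p2, contained):
        _, sol = contained
        w = p2.edw()
        assert w.lower_norm - 0.01 <= sol.plateau() <= w.upper_norm + 0.01

    def test_pontryagin_stationarity_at_interior_points(self, contained):
        problem, sol = contained
        interior = (sol.u_star > 1e-6) & (sol.u_star < 1.0 - 1e-6)
        resid = (problem.B * sol.u_star
                 - problem.params.delta * sol.S * sol.lambda1)
        assert np.max(np.abs(resid[interior])) < 1e-6 * problem.B

    def test_mesh_refinement_stability(self, p2, contained):
        problem, sol = contained
        fine = ControlProblem(params=p2.params, B=691.9, k_tol=p2.k0,
                              initial=problem.initial, T=1460.0,
                              steps_per_day=8)
        sol_f = afbsm_fixed_endpoint(fine)
        assert abs(sol_f.cost - sol.cost) < 1e-3 * sol.cost
        assert abs(sol_f.plateau() - sol.plateau()) < 0.005

    def test_local_optimality_against_projected_perturbations(
            self, contained):
        # bump the control by +/-1%, re-enforce the endpoint by a 1-D
        # correction (re-shooting theta), and check the cost cannot drop
        problem, sol = contained
        for sign in (+1.0, -1.0):
            bump = 1.0 + sign * 0.01 * np.exp(
                -((sol.grid - 730.0) / 200.0) ** 2)
            perturbed = np.clip(sol.u_star * bump, 0.0, 1.0)
            corrected = afbsm_fixed_endpoint(problem, u_init=perturbed)
            assert corrected.cost >= sol.cost * (1.0 - 1e-4)


class TestBSweepAndMED:
    def test_empty_grid_rejected(self, p2):
        with pytest.raises(ValueError):
            b_sweep(p2.params, p2.k0, 400.0, [])

    def test_plateau_monotone_in_weight_and_flattest_selected(self, p2):
        grid = [500.0, 691.9, 1000.0]
        sols, selected = b_sweep(p2.params, p2.k0, 1460.0, grid)
        plateaus = [sols[B].plateau() for B in grid]
        assert plateaus[0] >= plateaus[1] >= plateaus[2] - 1e-3
        # the published containment weight is the maximally flat schedule
        assert selected == 691.9

    def test_failed_weight_recorded_and_sweep_continues(self, p2):
        # B=300 drives the terminal state onto a secant precision cliff;
        # the sweep must record the failure and still solve the rest
        sols, selected = b_sweep(p2.params, p2.k0, 1460.0,
                                 [300.0, 691.9])
        assert isinstance(sols[300.0], ControlSolverError)
        assert selected == 691.9

    def test_med_is_the_plateau_and_in_unit_interval(self, contained):
        _, sol = contained
        med = med_from_solution(sol)
        assert 0.0 <= med <= 1.0
        assert med == pytest.approx(sol.plateau())

    def test_med_rejects_uncontained_solution(self, p2):
        problem = ControlProblem(params=p2.params, B=691.9, k_tol=p2.k0,
                                 initial=(0.99 * p2.k0, 0.01 * p2.k0),
                                 T=400.0)
        sol = fbsm(problem, lambda1_T=0.0)  # endpoint never enforced
        if sol.terminal_gap > 2e-3 * p2.k0:
            with pytest.raises(ValueError):
                med_from_solution(sol)
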