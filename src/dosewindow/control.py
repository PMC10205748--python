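"""Fixed-endpoint optimal control of the dose schedule.

Minimize the cost

    J(u) = int_0^T [ S + R + (B/2) u^2 ] dt

over normalized doses u(t) in [0, 1] driving the competition model, with
the terminal condition S(T) = K_tol (the tumor is handed over at the
tolerable volume, sensitive-only). Pontryagin's principle yields the
adjoint system (see :func:`adjoint_rhs`) with transversality
lambda2(T) = 0 and a free terminal value lambda1(T) = theta1 that must be
shot for, and the pointwise characterization

    u*(t) = min(1, max(0, delta * S(t) * lambda1(t) / B)).

The solver is the forward-backward sweep method (FBSM) — iterate forward
state integration, backward adjoint integration, and a damped control
update — wrapped in a secant iteration on theta1 that enforces the
endpoint (the adaptive FBSM). ``b_sweep`` scans the toxicity weight B;
larger B buys a lower plateau dose at the price of a terminal dose spike,
and the flattest member of the family is the containment schedule whose
plateau defines the minimum effective dose (MED).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fast import ctrl_backward, ctrl_forward
from .model import PatientParameters

__all__ = [
    "ControlProblem", "ControlSolution", "ControlSolverError",
    "adjoint_rhs", "control_update", "fbsm", "afbsm_fixed_endpoint",
    "b_sweep", "med_from_solution",
]


class ControlSolverError(RuntimeError):
    """FBSM divergence or secant stagnation; carries iteration history."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


@dataclass(frozen=True)
class ControlProblem:
    """Problem data for one containment run.

    B is the toxicity/cost weight of the quadratic dose penalty; k_tol the
    terminal sensitive-cell target (= tolerable tumor volume); T the
    horizon in days; initial the (S0, R0) state; steps_per_day sets the
    fixed FBSM mesh (forward and backward grids must coincide).
    """

    params: PatientParameters
    B: float
    k_tol: float
    initial: tuple[float, float]
    T: float = 1460.0
    steps_per_day: int = 4

    def __post_init__(self):
        if self.B <= 0:
            raise ValueError("control weight B must be positive")
        if not 0.0 < self.k_tol < self.params.K:
            raise ValueError("k_tol must lie in (0, K)")
        if self.T <= 0:
            raise ValueError("horizon must be positive")

    @property
    def n_nodes(self) -> int:
        return int(round(self.T * self.steps_per_day)) + 1

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, self.T, self.n_nodes)


@dataclass
class ControlSolution:
    grid: np.ndarray
    u_star: np.ndarray
    S: np.ndarray
    R: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda1_T: float
    terminal_gap: float
    cost: float
    sweeps: int
    secant_steps: int
    converged: bool

    @property
    def total(self) -> np.ndarray:
        return self.S + self.R

    def plateau(self, lo: float = 0.25, hi: float = 0.75,
                stat: str = "median") -> float:
        """Summary of u* over the middle of the horizon (default 25-75%)."""
        T = self.grid[-1]
        mask = (self.grid >= lo * T) & (self.grid <= hi * T)
        vals = self.u_star[mask]
        return float(np.median(vals) if stat == "median" else np.mean(vals))

    def summary(self) -> dict:
        return {
            "cost": self.cost,
            "plateau": self.plateau(),
            "terminal_gap": self.terminal_gap,
            "lambda1_T": self.lambda1_T,
            "sweeps": self.sweeps,
            "secant_steps": self.secant_steps,
            "converged": self.converged,
        }


def adjoint_rhs(state, adjoints, u: float, params: PatientParameters):
    """Adjoint derivatives (dlambda1/dt, dlambda2/dt).

    These are -dH/dS and -dH/dR for the Hamiltonian
    H = S + R + (B/2) u^2 + lambda . f(S, R, u); note dlambda2/dt carries
    no u term (the drug acts on S only).
    """
    S, R = state
    l1, l2 = adjoints
    r, K, delta, c = params.r, params.K, params.delta, params.c
    dl1 = -1.0 - l1 * (r * (1.0 - (2.0 * S + R) / K) - u * delta) \
        + l2 * r * c * R / K
    dl2 = -1.0 + l1 * r * S / K - l2 * r * (1.0 - (c * S + 2.0 * R) / K)
    return dl1, dl2


def control_update(S, lambda1, B: float, delta: float):
    """Pointwise optimal dose: clamp(delta*S*lambda1/B) to [0, 1]."""
    if B <= 0:
        raise ValueError("B must be positive")
    return np.clip(delta * np.asarray(S) * np.asarray(lambda1) / B,
                   0.0, 1.0)


def _cost(grid, S, R, u, B):
    return float(np.trapezoid(S + R + 0.5 * B * u ** 2, grid))


def fbsm(problem: ControlProblem, lambda1_T: float,
         u_init: np.ndarray | None = None,
         tol: float = 1e-8, max_sweeps: int = 500,
         damping: float = 0.5) -> ControlSolution:
    """Forward-backward sweep at a fixed terminal adjoint guess.

    The endpoint S(T)=K_tol is NOT enforced here; the sweep converges to
    the control consistent with ``lambda1_T``. The update is damped
    (u <- damping*u_old + (1-damping)*u_formula) — undamped sweeps
    oscillate. Divergence (control change growing for 10 consecutive
    sweeps) raises :class:`ControlSolverError` with the change history.
    """
    p = problem.params
    grid = problem.grid
    dt = grid[1] - grid[0]
    n = problem.n_nodes
    u = np.zeros(n) if u_init is None else np.asarray(u_init, float).copy()
    S0, R0 = problem.initial

    history = []
    grow_streak = 0
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        S, R = ctrl_forward(u, S0, R0, p.r, p.K, p.delta, p.c, dt)
        l1, l2 = ctrl_backward(S, R, u, lambda1_T, p.r, p.K, p.delta,
                               p.c, dt)
        u_formula = control_update(S, l1, problem.B, p.delta)
        u_new = damping * u + (1.0 - damping) * u_formula
        change = np.sum(np.abs(u_new - u)) / max(np.sum(np.abs(u_new)),
                                                 1e-12)
        history.append(change)
        u = u_new
        if change < tol:
            converged = True
            break
        if len(history) > 1 and change > history[-2]:
            grow_streak += 1
            if grow_streak >= 10:
                raise ControlSolverError(
                    f"FBSM diverging: control change grew for 10 "
                    f"consecutive sweeps (last change {change:.3e})",
                    history=history)
        else:
            grow_streak = 0
    # final consistent pass: state and adjoints for the returned control
    S, R = ctrl_forward(u, S0, R0, p.r, p.K, p.delta, p.c, dt)
    l1, l2 = ctrl_backward(S, R, u, lambda1_T, p.r, p.K, p.delta, p.c, dt)
    return ControlSolution(
        grid=grid, u_star=u, S=S, R=R, lambda1=l1, lambda2=l2,
        lambda1_T=lambda1_T,
        terminal_gap=float(abs(S[-1] - problem.k_tol)),
        cost=_cost(grid, S, R, u, problem.B),
        sweeps=sweeps, secant_steps=0, converged=converged)


def afbsm_fixed_endpoint(problem: ControlProblem,
                         theta_init: tuple[float, float] = (0.0, 10.0),
                         gap_tol_frac: float = 1e-3,
                         max_secant: int = 60,
                         u_init: np.ndarray | None = None,
                         fbsm_kwargs: dict | None = None) -> ControlSolution:
    """Adaptive FBSM: secant shooting on lambda1(T) to hit S(T)=K_tol.

    Iterates g(theta) = S(T; theta) - K_tol to below
    ``gap_tol_frac * K_tol``; each FBSM call is warm-started from the
    previous control. Raises :class:`ControlSolverError` with the last two
    (theta, gap) pairs on stagnation.
    """
    kwargs = fbsm_kwargs or {}
    gap_tol = gap_tol_frac * problem.k_tol

    theta0, theta1 = float(theta_init[0]), float(theta_init[1])
    sol0 = fbsm(problem, theta0, u_init=u_init, **kwargs)
    g0 = sol0.S[-1] - problem.k_tol
    total_sweeps = sol0.sweeps
    sol1 = fbsm(problem, theta1, u_init=sol0.u_star, **kwargs)
    g1 = sol1.S[-1] - problem.k_tol
    total_sweeps += sol1.sweeps

    best = min((sol0, g0), (sol1, g1), key=lambda t: abs(t[1]))
    for step in range(1, max_secant + 1):
        if abs(g1) < gap_tol:
            sol1.terminal_gap = abs(g1)
            sol1.secant_steps = step - 1
            sol1.sweeps = total_sweeps
            return sol1
        denom = g1 - g0
        if abs(denom) < 1e-14 * max(abs(g1), 1.0):
            theta2 = theta1 + max(1.0, abs(theta1))  # stagnated: kick
        else:
            theta2 = theta1 - g1 * (theta1 - theta0) / denom
        sol2 = fbsm(problem, theta2, u_init=sol1.u_star, **kwargs)
        g2 = sol2.S[-1] - problem.k_tol
        total_sweeps += sol2.sweeps
        theta0, g0 = theta1, g1
        theta1, g1, sol1 = theta2, g2, sol2
        if abs(g1) < abs(best[1]):
            best = (sol1, g1)
    raise ControlSolverError(
        f"secant failed to reach |S(T)-K_tol| < {gap_tol:.3g} in "
        f"{max_secant} steps; last pairs "
        f"({theta0:.6g}, {g0:.6g}), ({theta1:.6g}, {g1:.6g})",
        history=[(theta0, g0), (theta1, g1)])


def b_sweep(params: PatientParameters, k_tol: float, T: float,
            B_grid, initial: tuple[float, float] | None = None,
            steps_per_day: int = 4,
            tail_frac: float = 0.1,
            **afbsm_kwargs):
    """Solve the fixed-endpoint problem across a grid of weights B.

    Returns (solutions, selected_B): ``solutions`` maps B to a
    ControlSolution or to the error that killed it; ``selected_B``
    minimizes the terminal dose spike (variance of u* over the last
    ``tail_frac`` of the horizon) — the maximally flat, i.e. containment,
    schedule. Larger B yields a lower plateau with a compensating terminal
    rise.
    """
    B_grid = list(B_grid)
    if not B_grid:
        raise ValueError("B grid must be non-empty")
    if sorted(B_grid) != B_grid or min(B_grid) <= 0:
        raise ValueError("B grid must be positive and sorted ascending")
    if initial is None:
        initial = (0.99 * k_tol, 0.01 * k_tol)
    solutions: dict[float, ControlSolution | Exception] = {}
    warm = None
    best_B, best_spike = None, np.inf
    for B in B_grid:
        problem = ControlProblem(params=params, B=B, k_tol=k_tol,
                                 initial=initial, T=T,
                                 steps_per_day=steps_per_day)
        try:
            sol = afbsm_fixed_endpoint(problem, u_init=warm,
                                       **afbsm_kwargs)
        except ControlSolverError as err:
            solutions[B] = err
            continue
        solutions[B] = sol
        warm = sol.u_star
        tail = sol.grid >= (1.0 - tail_frac) * T
        spike = float(np.var(sol.u_star[tail]))
        if spike < best_spike:
            best_spike, best_B = spike, B
    if best_B is None:
        raise ControlSolverError("every B in the sweep failed")
    return solutions, best_B


def med_from_solution(solution: ControlSolution,
                      gap_tol_frac: float = 2e-3) -> float:
    """Minimum effective dose: the plateau (median u* over the middle 50%)
    of a converged, contained solution."""
    if not solution.converged:
        raise ValueError("solution did not converge; MED undefined")
    k_ref = max(solution.S[-1], 1e-12)
    if solution.terminal_gap > gap_tol_frac * k_ref:
        raise ValueError(f"solution is not contained (terminal gap "
                         f"{solution.terminal_gap:.3g}); MED undefined")
    return solution.plateau()
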