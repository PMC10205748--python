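"""Two-population logistic competition model of tumor growth under therapy.

The model tracks a drug-sensitive burden ``S`` and a drug-resistant burden
``R`` (both in the units of the serologic marker, IU/L-equivalents) sharing a
carrying capacity ``K``:

.. math::

    dS/dt = r (1 - (S + R)/K) S - u \\delta S,
    \\qquad
    dR/dt = r (1 - (c S + R)/K) R,

where ``r`` is the common intrinsic growth rate (per day), ``delta`` the
drug-induced death rate of sensitive cells at the maximum tolerated dose
(MTD), ``u`` in [0, 1] the normalized dose (fraction of MTD) and ``c > 1``
the competitive strength of sensitive over resistant cells.

Writing ``delta_eff = u * delta``, the phase portrait falls into three
regimes:

* Case I, ``delta_eff > r``: only the resistant-only state ``(0, K)`` is
  stable — therapy is self-defeating.
* Case II, ``r > delta_eff > r (c-1)/c``: a sensitive-only state exists but
  is unstable; every interior trajectory still ends at ``(0, K)``
  (decline-then-relapse under MTD).
* Case III, ``r (c-1)/c > delta_eff > 0``: bistability. The sensitive-only
  state ``(K (1 - delta_eff/r), 0)`` and ``(0, K)`` are both stable, and an
  unstable coexistence state sits on the separatrix between their basins.

Containment at a tolerable tumor volume ``K_tol`` therefore requires the
effective death rate to sit in the *effective dose window*

.. math::

    r (1 - K_{tol}/K) < \\delta_{eff} < r (1 - 1/c),

computed by :func:`effective_dose_window`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._fast import integrate_states

__all__ = [
    "PatientParameters",
    "TumorState",
    "Trajectory",
    "Equilibrium",
    "EquilibriumSet",
    "DynamicsCase",
    "EDWindow",
    "vector_field",
    "jacobian",
    "equilibria",
    "classify_dynamics",
    "effective_dose_window",
    "k0_from_lower_bound",
    "simulate",
    "basin_membership",
    "separatrix_curve",
]

PARAM_NAMES = ("r", "K", "delta", "c")


@dataclass(frozen=True)
class PatientParameters:
    """Model parameters for one patient.

    Attributes
    ----------
    r : float
        Intrinsic growth rate of both populations (per day).
    K : float
        Shared carrying capacity (burden units, IU/L-equivalent).
    delta : float
        Drug-induced death rate of sensitive cells at MTD (per day).
    c : float
        Competition coefficient of sensitive over resistant cells
        (dimensionless, strictly greater than 1).
    """

    r: float
    K: float
    delta: float
    c: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name!r} must be finite and "
                                 f"strictly positive, got {value!r}")
        if self.c <= 1:
            raise ValueError(f"competition coefficient c must exceed 1 "
                             f"(got c={self.c!r})")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.K, self.delta, self.c])

    @classmethod
    def from_array(cls, p: Sequence[float]) -> "PatientParameters":
        return cls(*[float(v) for v in p])


@dataclass(frozen=True)
class TumorState:
    """Non-negative (sensitive, resistant) burden pair."""

    S: float
    R: float

    def __post_init__(self):
        if self.S < 0 or self.R < 0:
            raise ValueError(f"state components must be non-negative, got "
                             f"(S={self.S!r}, R={self.R!r})")

    @property
    def total(self) -> float:
        return self.S + self.R

    def as_tuple(self) -> tuple[float, float]:
        return (self.S, self.R)


def _as_state(initial) -> TumorState:
    if isinstance(initial, TumorState):
        return initial
    S, R = initial
    return TumorState(float(S), float(R))


@dataclass
class Trajectory:
    """Time-indexed solution path with the dose applied at each node."""

    times: np.ndarray
    S: np.ndarray
    R: np.ndarray
    dose: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if np.any(self.S < 0) or np.any(self.R < 0):
            raise ValueError("trajectory states must be non-negative")

    @property
    def total(self) -> np.ndarray:
        return self.S + self.R

    def final_state(self) -> TumorState:
        return TumorState(float(self.S[-1]), float(self.R[-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_days": self.times,
            "S": self.S,
            "R": self.R,
            "total": self.total,
            "dose": self.dose,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class Equilibrium:
    S: float
    R: float
    stability: str  # "stable" | "unstable" | "nonexistent" | "degenerate"

    @property
    def exists(self) -> bool:
        return self.stability != "nonexistent"


@dataclass(frozen=True)
class EquilibriumSet:
    trivial: Equilibrium
    s_only: Equilibrium
    r_only: Equilibrium
    coexistence: Equilibrium

    def __iter__(self):
        return iter((self.trivial, self.s_only, self.r_only,
                     self.coexistence))


@dataclass(frozen=True)
class DynamicsCase:
    """Regime label for a given effective death rate u*delta."""

    label: str  # "I" | "II" | "III" | "degenerate" | "untreated"
    effective_delta: float


@dataclass(frozen=True)
class EDWindow:
    """Effective dose window at a tolerable volume ``k_tol``.

    ``lower``/``upper`` are on the death-rate scale (per day);
    ``lower_norm``/``upper_norm`` are the same bounds divided by the MTD
    death rate ``delta`` and clamped to [0, 1] (fractions of MTD).
    """

    lower: float
    upper: float
    k_tol: float
    nonempty: bool
    lower_norm: float
    upper_norm: float

    def to_dict(self) -> dict:
        return {
            "lower_per_day": self.lower,
            "upper_per_day": self.upper,
            "lower_norm": self.lower_norm,
            "upper_norm": self.upper_norm,
            "k_tol": self.k_tol,
            "nonempty": self.nonempty,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _check_dose(u: float) -> float:
    u = float(u)
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"normalized dose must lie in [0, 1], got {u!r}")
    return u


def vector_field(state, params: PatientParameters, u: float):
    """Right-hand side (dS/dt, dR/dt) at a state under normalized dose u."""
    st = _as_state(state)
    u = _check_dose(u)
    r, K, delta, c = params.r, params.K, params.delta, params.c
    S, R = st.S, st.R
    dS = r * (1.0 - (S + R) / K) * S - u * delta * S
    dR = r * (1.0 - (c * S + R) / K) * R
    return dS, dR


def jacobian(state, params: PatientParameters, u: float) -> np.ndarray:
    """Analytic Jacobian of the vector field at a state."""
    st = _as_state(state)
    u = _check_dose(u)
    r, K, delta, c = params.r, params.K, params.delta, params.c
    S, R = st.S, st.R
    de = u * delta
    return np.array([
        [r * (1.0 - (2.0 * S + R) / K) - de, -r * S / K],
        [-r * c * R / K, r * (1.0 - (c * S + 2.0 * R) / K)],
    ])


def classify_dynamics(params: PatientParameters, u: float,
                      rtol: float = 1e-12) -> DynamicsCase:
    """Classify the treated dynamics by the effective death rate u*delta.

    Boundary equalities (within relative tolerance ``rtol``) are labelled
    ``"degenerate"`` rather than silently assigned; u = 0 is labelled
    ``"untreated"``.
    """
    u = _check_dose(u)
    de = u * params.delta
    if de == 0.0:
        return DynamicsCase("untreated", 0.0)
    r, c = params.r, params.c
    threshold = r * (c - 1.0) / c
    if abs(de - r) <= rtol * r or abs(de - threshold) <= rtol * r:
        return DynamicsCase("degenerate", de)
    if de > r:
        return DynamicsCase("I", de)
    if de > threshold:
        return DynamicsCase("II", de)
    return DynamicsCase("III", de)


def equilibria(params: PatientParameters, u: float) -> EquilibriumSet:
    """The four equilibria with existence and stability labels.

    Coordinates follow the closed forms with ``delta`` replaced by
    ``u*delta``; stability follows the Case I/II/III classification (the
    test suite cross-checks the labels against Jacobian eigenvalues).
    """
    u = _check_dose(u)
    r, K, delta, c = params.r, params.K, params.delta, params.c
    de = u * delta
    case = classify_dynamics(params, u)

    trivial = Equilibrium(0.0, 0.0, "unstable")

    if de < r:
        s_only_state = (K * (1.0 - de / r), 0.0)
        if case.label == "III":
            s_only = Equilibrium(*s_only_state, "stable")
        elif case.label == "untreated":
            s_only = Equilibrium(*s_only_state, "stable")
        elif case.label == "II":
            s_only = Equilibrium(*s_only_state, "unstable")
        else:  # degenerate boundary
            s_only = Equilibrium(*s_only_state, "degenerate")
    else:
        s_only = Equilibrium(np.nan, np.nan, "nonexistent")

    # R-only state (0, K): stable whenever treatment is on; with u = 0 its
    # leading eigenvalue vanishes (non-hyperbolic), so it is flagged
    # degenerate rather than assigned.
    r_only = Equilibrium(0.0, K,
                         "degenerate" if case.label == "untreated"
                         else "stable")

    if 0.0 < de < r * (c - 1.0) / c:
        Sx = de * K / (r * (c - 1.0))
        Rx = c * K / (c - 1.0) * (1.0 - de / r - 1.0 / c)
        label = "unstable" if case.label == "III" else "degenerate"
        coexistence = Equilibrium(Sx, Rx, label)
    else:
        coexistence = Equilibrium(np.nan, np.nan, "nonexistent")

    return EquilibriumSet(trivial, s_only, r_only, coexistence)


def effective_dose_window(params: PatientParameters,
                          k_tol: float) -> EDWindow:
    """Effective dose window for containment at tolerable volume ``k_tol``.

    Bounds on the death-rate scale are ``r (1 - k_tol/K)`` (lower) and
    ``r (1 - 1/c)`` (upper); the window is nonempty iff ``k_tol > K/c``.

    Raises
    ------
    ValueError
        If ``k_tol`` is not in (0, K); a tolerable volume at or above the
        carrying capacity is vacuous.
    """
    k_tol = float(k_tol)
    if not 0.0 < k_tol < params.K:
        raise ValueError(f"k_tol must lie in (0, K={params.K}), "
                         f"got {k_tol!r}")
    lower = params.r * (1.0 - k_tol / params.K)
    upper = params.r * (1.0 - 1.0 / params.c)
    return EDWindow(
        lower=lower,
        upper=upper,
        k_tol=k_tol,
        nonempty=lower < upper,
        lower_norm=float(np.clip(lower / params.delta, 0.0, 1.0)),
        upper_norm=float(np.clip(upper / params.delta, 0.0, 1.0)),
    )


def k0_from_lower_bound(params: PatientParameters,
                        printed_lower: float) -> float:
    """Invert the lower window bound for the implied initial burden K_0.

    ``printed_lower = r (1 - K_0/K)`` gives ``K_0 = K (1 - printed_lower/r)``.
    """
    printed_lower = float(printed_lower)
    if not 0.0 <= printed_lower < params.r:
        raise ValueError(f"lower bound must lie in [0, r={params.r}), "
                         f"got {printed_lower!r}")
    return params.K * (1.0 - printed_lower / params.r)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries solver diagnostics."""


def simulate(params: PatientParameters,
             dose_policy: float | Callable[[float, tuple], float],
             initial, horizon: float,
             t_eval: np.ndarray | None = None,
             rtol: float = 1e-8,
             atol_frac: float = 1e-10) -> Trajectory:
    """Integrate the model under a dose policy over ``[0, horizon]``.

    ``dose_policy`` is either a constant in [0, 1] or a callable
    ``policy(t, (S, R)) -> u``; smooth policies only — event-driven on/off
    schedules belong to :mod:`dosewindow.adaptive`. Adaptive RK45 at
    ``rtol=1e-8``, ``atol=1e-10*K``: bistability near the separatrix
    demands tight tolerances.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    st = _as_state(initial)
    if callable(dose_policy):
        policy = dose_policy
    else:
        u_const = _check_dose(dose_policy)
        policy = lambda t, y: u_const  # noqa: E731

    r, K, delta, c = params.r, params.K, params.delta, params.c

    def rhs(t, y):
        S, R = max(y[0], 0.0), max(y[1], 0.0)
        u = float(np.clip(policy(t, (S, R)), 0.0, 1.0))
        return [r * (1.0 - (S + R) / K) * S - u * delta * S,
                r * (1.0 - (c * S + R) / K) * R]

    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, max(int(horizon), 2) + 1)
    sol = solve_ivp(rhs, (0.0, horizon), [st.S, st.R], t_eval=t_eval,
                    method="RK45", rtol=rtol, atol=atol_frac * K)
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message} "
                               f"(reached t={sol.t[-1] if len(sol.t) else 0})")
    S = np.clip(sol.y[0], 0.0, None)
    R = np.clip(sol.y[1], 0.0, None)
    dose = np.array([float(np.clip(policy(t, (s, rr)), 0.0, 1.0))
                     for t, s, rr in zip(sol.t, S, R)])
    return Trajectory(sol.t, S, R, dose)


def basin_membership(params: PatientParameters, u: float, initial,
                     horizon: float | None = None,
                     tol_frac: float = 1e-3,
                     dt: float = 0.05) -> str:
    """Which attractor a Case-III initial condition converges to.

    Returns ``"S_only"``, ``"R_only"`` or ``"undetermined"`` (horizon
    exhausted, e.g. on the separatrix). Cases I/II have a single interior
    attractor and return ``"R_only"`` immediately. Convergence is declared
    within ``tol_frac*K`` (Euclidean) of an attractor; the horizon defaults
    to ``max(4000, 30/r)`` days to ride out the slow dynamics near the
    saddle.
    """
    u = _check_dose(u)
    case = classify_dynamics(params, u)
    if case.label in ("I", "II"):
        return "R_only"
    st = _as_state(initial)
    r, K, delta, c = params.r, params.K, params.delta, params.c
    de = u * delta
    if horizon is None:
        horizon = max(4000.0, 30.0 / r)
    s_attr = np.array([K * (1.0 - de / r), 0.0])
    r_attr = np.array([0.0, K])
    tol = tol_frac * K
    t_out = np.arange(5.0, horizon + 5.0, 5.0)
    S, R = integrate_states(st.S, st.R, 0.0, t_out, r, K, de, c, dt)
    ds = np.hypot(S - s_attr[0], R - s_attr[1])
    dr = np.hypot(S - r_attr[0], R - r_attr[1])
    hit_s = np.nonzero(ds < tol)[0]
    hit_r = np.nonzero(dr < tol)[0]
    if hit_s.size and (not hit_r.size or hit_s[0] <= hit_r[0]):
        return "S_only"
    if hit_r.size:
        return "R_only"
    return "undetermined"


def separatrix_curve(params: PatientParameters, u: float,
                     n_points: int = 33,
                     bracket_frac: float = 1e-6,
                     basin_kwargs: dict | None = None) -> np.ndarray:
    """Locate the Case-III separatrix as a polyline in (S, R) space.

    For each of ``n_points`` vertical sections S = const the basin boundary
    is bisected in R between a sensitive-only point (small R) and a
    resistant-only point (large R); membership is monotone in R at fixed S.
    The sections span (0, S_only equilibrium) and include the coexistence
    S-coordinate, so the returned curve passes near the saddle. Sections
    where both bracket ends classify alike are dropped.

    Returns an (m, 2) array of (S, R) points, m <= n_points.
    """
    u = _check_dose(u)
    case = classify_dynamics(params, u)
    if case.label != "III":
        raise ValueError(f"separatrix requires Case III dynamics, "
                         f"got Case {case.label}")
    eq = equilibria(params, u)
    kwargs = basin_kwargs or {}
    K = params.K
    s_grid = np.linspace(0.03 * eq.s_only.S, 0.97 * eq.s_only.S, n_points)
    # insert the saddle's S-coordinate so the curve is anchored there
    s_grid = np.sort(np.append(s_grid, eq.coexistence.S))[:n_points]
    points = []
    for S in s_grid:
        lo, hi = 1e-6 * K, 1.2 * K
        if basin_membership(params, u, (S, lo), **kwargs) != "S_only":
            continue
        if basin_membership(params, u, (S, hi), **kwargs) != "R_only":
            continue
        while hi - lo > bracket_frac * K:
            mid = 0.5 * (lo + hi)
            side = basin_membership(params, u, (S, mid), **kwargs)
            if side == "R_only":
                hi = mid
            else:  # S_only or undetermined (on the boundary): move up
                lo = mid
        points.append((S, 0.5 * (lo + hi)))
    return np.array(points)
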