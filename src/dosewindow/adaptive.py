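"""Adaptive therapy: on/off scheduling, time to progression, dose sweeps.

The schedule applies a fixed fraction of MTD until the total burden drops
below ``pause_level`` times the initial burden, then pauses until the
burden regrows to 99.9% of the tolerable volume ``k_tol``, and repeats.
``k_tol`` doubles as the progression threshold: time to progression (TTP)
is the first time the total burden strictly exceeds it (the start, where
the burden may equal ``k_tol`` exactly, is exempt); TTP is the degenerate
value 1 when the burden grows from treatment start, and the horizon when
the tumor never progresses.

Sweeping the (dose, pause) grid yields a TTP heatmap; the maximal
contiguous dose band with full-horizon TTP at *every* pause level is the
adaptive-therapy effective dose window (EDW_AT), whose lower edge matches
the normalized continuous-therapy window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._fast import at_run, at_ttp
from .model import PatientParameters, Trajectory

__all__ = ["ATPolicy", "ATOutcome", "simulate_at", "ttp_heatmap",
           "edw_at", "heatmap_frame"]

_DT = 0.05       # RK4 step (days)
_TIME_TOL = 1e-6  # switching-time bisection tolerance (days)


@dataclass(frozen=True)
class ATPolicy:
    """Normalized dose, pause level (fraction of initial burden) and the
    tolerable-volume threshold used for both resumption and progression."""

    normalized_dose: float
    pause_level: float
    k_tol: float

    def __post_init__(self):
        if not 0.0 <= self.normalized_dose <= 1.0:
            raise ValueError("normalized dose must lie in [0, 1]")
        if not 0.0 <= self.pause_level <= 1.0:
            raise ValueError("pause level must lie in [0, 1]")
        if self.k_tol <= 0:
            raise ValueError("k_tol must be positive")


@dataclass
class ATOutcome:
    trajectory: Trajectory
    switch_times: np.ndarray
    ttp: float
    progressed: bool

    def __post_init__(self):
        if np.any(np.diff(self.switch_times) <= 0):
            raise ValueError("switch times must be strictly increasing")


def default_initial(k_tol: float,
                    resistant_fraction: float = 0.01) -> tuple[float, float]:
    """Start at the tolerable volume with a 1% resistant fraction."""
    return ((1.0 - resistant_fraction) * k_tol, resistant_fraction * k_tol)


def simulate_at(params: PatientParameters, policy: ATPolicy, initial,
                horizon: float = 1460.0, dt: float = _DT) -> ATOutcome:
    """Event-driven hybrid simulation of one adaptive-therapy schedule.

    Treatment starts ON. Switching times are localized by bisection to
    1e-6 day; the recorded dose is the applied regime at each node.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    S0, R0 = (initial.S, initial.R) if hasattr(initial, "S") else initial
    (t, S, R, u, _n, switches, n_switch, ttp, progressed) = at_run(
        float(S0), float(R0), params.r, params.K, params.delta, params.c,
        policy.normalized_dose, policy.pause_level, policy.k_tol,
        float(horizon), dt, _TIME_TOL)
    if n_switch > len(switches):
        raise RuntimeError(f"schedule chattering: {n_switch} switches")
    # drop any duplicated time nodes produced by event alignment
    keep = np.concatenate([[True], np.diff(t) > 0])
    traj = Trajectory(t[keep], S[keep], R[keep], u[keep])
    return ATOutcome(trajectory=traj, switch_times=switches,
                     ttp=float(ttp), progressed=bool(progressed))


def ttp_heatmap(params: PatientParameters, dose_grid, pause_grid,
                k_tol: float, horizon: float = 1460.0,
                initial=None, dt: float = _DT) -> np.ndarray:
    """TTP (days) for each (pause, dose) cell; rows = pause levels."""
    dose_grid = np.asarray(dose_grid, float)
    pause_grid = np.asarray(pause_grid, float)
    if np.any((dose_grid < 0) | (dose_grid > 1)):
        raise ValueError("doses must lie in [0, 1]")
    if np.any((pause_grid < 0) | (pause_grid > 1)):
        raise ValueError("pause levels must lie in [0, 1]")
    if initial is None:
        initial = default_initial(k_tol)
    S0, R0 = (initial.S, initial.R) if hasattr(initial, "S") else initial
    out = np.empty((len(pause_grid), len(dose_grid)))
    for i, pause in enumerate(pause_grid):
        for j, dose in enumerate(dose_grid):
            ttp, _prog, n_switch = at_ttp(
                float(S0), float(R0), params.r, params.K, params.delta,
                params.c, float(dose), float(pause), float(k_tol),
                float(horizon), dt, _TIME_TOL)
            if ttp < 0:
                raise RuntimeError(f"schedule chattering at dose={dose}, "
                                   f"pause={pause} ({n_switch} switches)")
            out[i, j] = ttp
    return out


def edw_at(heatmap: np.ndarray, dose_grid, horizon: float):
    """Maximal contiguous dose interval with TTP == horizon at every pause.

    Returns (lower, upper) dose bounds, or None when no dose achieves
    full-horizon TTP across all pause levels.
    """
    dose_grid = np.asarray(dose_grid, float)
    full = np.all(heatmap >= horizon, axis=0)
    if not np.any(full):
        return None
    best = (0, -1)  # (length, start)
    start = None
    for j, ok in enumerate(np.append(full, False)):
        if ok and start is None:
            start = j
        elif not ok and start is not None:
            if j - start > best[0]:
                best = (j - start, start)
            start = None
    length, start = best
    return (float(dose_grid[start]), float(dose_grid[start + length - 1]))


def heatmap_frame(heatmap: np.ndarray, dose_grid,
                  pause_grid) -> pd.DataFrame:
    """Rows = pause levels, columns = doses (CSV-friendly)."""
    return pd.DataFrame(heatmap,
                        index=pd.Index(pause_grid, name="pause_level"),
                        columns=pd.Index(dose_grid, name="dose"))
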