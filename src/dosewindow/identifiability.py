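"""Practical identifiability diagnostics for a calibrated fit.

Two complementary diagnostics, mirroring standard ODE-model practice:

* Fisher information: a finite-difference sensitivity matrix M of the
  states (S, R) at the observation times with respect to (r, K, delta, c),
  central differences at (1 +/- eps) p-hat with eps = 0.001; the FIM is
  F = M^T M and full rank (4) is necessary for practical identifiability.
* Profile likelihood: each parameter is swept over +/- 20% of its estimate
  while the other three are re-fitted; an interior minimum whose endpoints
  clear the minimum by more than the chi^2_1 95% half-threshold (1.92 on
  the NLL scale) counts as identifiable in that direction.

A multi-start uniqueness check stands in for symbolic structural
analysis: dispersed Nelder-Mead starts must agree in both NLL and
parameters for the fit to be called unique.

The two diagnostics can disagree (full rank but a flat profile), so the
combined verdict requires both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fast import integrate_states
from .calibration import (_params_from_x, _x_from_params,
                          negative_log_likelihood)
from .cohort import ObservedSeries
from .model import PARAM_NAMES, PatientParameters, TumorState
from scipy.optimize import minimize

__all__ = [
    "SensitivityMatrix", "ProfileCurve", "IdentifiabilityReport",
    "sensitivity_matrix", "fim", "fim_rank", "profile_likelihood",
    "empirical_uniqueness_check", "identifiability_report",
]


@dataclass
class SensitivityMatrix:
    """Stacked state sensitivities: rows (S, R) per time, columns params."""

    matrix: np.ndarray  # (2N, 4)
    times: np.ndarray
    epsilon: float
    param_names: tuple = PARAM_NAMES


def sensitivity_matrix(params: PatientParameters, times, initial,
                       epsilon: float = 1e-3,
                       dt_max: float = 0.05) -> SensitivityMatrix:
    """Central-difference sensitivities d(S,R)/dp at the observation times.

    Each parameter p_i is perturbed to (1 +/- epsilon) p_i and the model is
    re-integrated under MTD; the column is the central difference. Both
    states are used as observables. Sensitivities are raw (unscaled).
    """
    if not 0.0 < epsilon < 0.1:
        raise ValueError(f"epsilon must lie in (0, 0.1), got {epsilon!r}")
    times = np.asarray(times, dtype=float)
    if isinstance(initial, TumorState):
        S0, R0 = initial.S, initial.R
    else:
        S0, R0 = float(initial[0]), float(initial[1])
    p = params.as_array()
    N = len(times)
    M = np.empty((2 * N, 4))
    for i in range(4):
        cols = []
        for sign in (+1.0, -1.0):
            q = p.copy()
            q[i] = (1.0 + sign * epsilon) * p[i]
            try:
                pe = PatientParameters.from_array(q)
                S, R = integrate_states(S0, R0, float(times[0]), times,
                                        pe.r, pe.K, pe.delta, pe.c, dt_max)
            except (ValueError, FloatingPointError) as err:
                raise RuntimeError(
                    f"integration failed while perturbing parameter "
                    f"{PARAM_NAMES[i]!r}: {err}") from err
            cols.append(np.column_stack([S, R]).ravel())  # S,R per time
        M[:, i] = (cols[0] - cols[1]) / (2.0 * epsilon * p[i])
    if not np.all(np.isfinite(M)):
        raise RuntimeError("non-finite sensitivity entries")
    return SensitivityMatrix(matrix=M, times=times, epsilon=epsilon)


def fim(sm: SensitivityMatrix | np.ndarray) -> np.ndarray:
    M = sm.matrix if isinstance(sm, SensitivityMatrix) else np.asarray(sm)
    return M.T @ M


def fim_rank(F: np.ndarray, tau: float = 1e-12):
    """Numerical rank: singular values above tau * sigma_max.

    Central differencing at eps=0.001 leaves ~1e-6 relative noise in the
    sensitivity matrix M; in F = M^T M singular values square, so the
    numerically-zero directions of F sit near (1e-6)^2 = 1e-12 of
    sigma_max, which sets tau.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] != F.shape[1]:
        raise ValueError("FIM must be square")
    scale = np.max(np.abs(F)) or 1.0
    if np.max(np.abs(F - F.T)) > 1e-8 * scale:
        raise ValueError("FIM is not symmetric within tolerance")
    sv = np.linalg.svd(F, compute_uv=False)
    if sv[0] == 0.0:
        return 0, sv
    rank = int(np.sum(sv > tau * sv[0]))
    return rank, sv


@dataclass
class ProfileCurve:
    param_name: str
    grid: np.ndarray
    nll: np.ndarray
    failed: np.ndarray  # flags for grid points whose inner fit failed
    fit_nll: float

    @property
    def min_index(self) -> int:
        return int(np.nanargmin(self.nll))

    @property
    def has_interior_minimum(self) -> bool:
        """Interior minimum with both endpoints above min + 1.92."""
        i = self.min_index
        if i == 0 or i == len(self.grid) - 1:
            return False
        m = self.nll[i]
        return bool(self.nll[0] > m + 1.92 and self.nll[-1] > m + 1.92)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({self.param_name: self.grid, "nll": self.nll,
                             "inner_fit_failed": self.failed})


def _inner_refit(series, fixed_index, fixed_value, x_free_start,
                 resistant_fraction, maxiter=600):
    """Minimize NLL over the three parameters not being profiled."""
    free = [j for j in range(4) if j != fixed_index]

    def unpack(xf):
        x = np.empty(4)
        x[free] = xf
        # fixed parameter enters on its natural scale
        if fixed_index == 3:
            if fixed_value <= 1.0:
                return None
            x[3] = np.log(fixed_value - 1.0)
        else:
            x[fixed_index] = np.log(fixed_value)
        return _params_from_x(x)

    def objective(xf):
        p = unpack(xf)
        if p is None:
            return np.inf
        return negative_log_likelihood(series, p,
                                       resistant_fraction=resistant_fraction)

    res = minimize(objective, x_free_start, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-7,
                            "maxiter": maxiter, "maxfev": maxiter})
    return res


def profile_likelihood(series: ObservedSeries,
                       estimate: PatientParameters,
                       param_index: int,
                       eta: float = 0.2,
                       n_grid: int = 41,
                       resistant_fraction: float = 0.01) -> ProfileCurve:
    """Profile of one parameter over [p(1-eta), p(1+eta)].

    The sweep is warm-started outward from the estimate in both directions
    (each grid point starts the inner three-parameter refit from its
    neighbor's solution). Failed inner fits are flagged and the curve
    continues.
    """
    p_hat = estimate.as_array()
    center = p_hat[param_index]
    grid = np.linspace(center * (1.0 - eta), center * (1.0 + eta), n_grid)
    x_hat = _x_from_params(estimate)
    free = [j for j in range(4) if j != param_index]
    nll = np.full(n_grid, np.nan)
    failed = np.zeros(n_grid, dtype=bool)

    mid = int(np.argmin(np.abs(grid - center)))
    for direction in (+1, -1):
        x_start = x_hat[free].copy()
        idxs = range(mid, n_grid) if direction > 0 else range(mid - 1, -1, -1)
        for i in idxs:
            res = _inner_refit(series, param_index, grid[i], x_start,
                               resistant_fraction)
            if np.isfinite(res.fun):
                nll[i] = res.fun
                x_start = res.x
            else:
                failed[i] = True
    fit_nll = negative_log_likelihood(series, estimate,
                                      resistant_fraction=resistant_fraction)
    return ProfileCurve(param_name=PARAM_NAMES[param_index], grid=grid,
                        nll=nll, failed=failed, fit_nll=fit_nll)


@dataclass
class UniquenessVerdict:
    verdict: str  # "unique" | "not_unique"
    best_nll: float
    n_within_nll: int
    max_param_spread: float


def empirical_uniqueness_check(series: ObservedSeries,
                               n_starts: int = 20,
                               seed: int = 0,
                               resistant_fraction: float = 0.01,
                               nll_rtol: float = 0.01,
                               param_rtol: float = 0.05,
                               maxiter: int = 2000) -> UniquenessVerdict:
    """Multi-start agreement check standing in for structural analysis.

    Runs Nelder-Mead from ``n_starts`` dispersed starting points; the fit
    is "unique" if every converged run within ``nll_rtol`` of the best NLL
    also agrees with the best parameters to within ``param_rtol``
    (relative, per parameter).
    """
    if n_starts < 20:
        raise ValueError("need at least 20 starts for a meaningful verdict")
    rng = np.random.default_rng(seed)
    vmax = float(series.burdens.max())

    def objective(x):
        p = _params_from_x(x)
        if p is None:
            return np.inf
        return negative_log_likelihood(series, p,
                                       resistant_fraction=resistant_fraction)

    results = []
    for _ in range(n_starts):
        r0 = rng.uniform(np.log(0.03), np.log(0.6))
        k0 = rng.uniform(np.log(0.5 * vmax), np.log(4.0 * vmax))
        d0 = rng.uniform(np.log(0.01), np.log(0.6))
        c0 = rng.uniform(np.log(0.05), np.log(5.0))  # log(c-1)
        res = minimize(objective, np.array([r0, k0, d0, c0]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-8,
                                "maxiter": maxiter, "maxfev": maxiter})
        if np.isfinite(res.fun):
            results.append((res.fun, _params_from_x(res.x)))
    if not results:
        return UniquenessVerdict("not_unique", np.inf, 0, np.inf)
    results.sort(key=lambda t: t[0])
    best_nll, best_p = results[0]
    scale = max(abs(best_nll), 1.0)
    close = [p for f, p in results if f - best_nll <= nll_rtol * scale]
    ref = best_p.as_array()
    spread = 0.0
    for p in close:
        spread = max(spread,
                     float(np.max(np.abs(p.as_array() - ref) / ref)))
    verdict = "unique" if spread <= param_rtol else "not_unique"
    return UniquenessVerdict(verdict, float(best_nll), len(close),
                             float(spread))


@dataclass
class IdentifiabilityReport:
    fim: np.ndarray
    singular_values: np.ndarray
    rank: int
    profiles: dict
    identifiable: bool

    def to_dict(self) -> dict:
        return {
            "fim": self.fim.tolist(),
            "singular_values": self.singular_values.tolist(),
            "rank": self.rank,
            "profiles": {
                name: {"grid": pc.grid.tolist(), "nll": pc.nll.tolist(),
                       "interior_minimum": pc.has_interior_minimum}
                for name, pc in self.profiles.items()
            },
            "identifiable": self.identifiable,
        }


def identifiability_report(series: ObservedSeries,
                           estimate: PatientParameters,
                           resistant_fraction: float = 0.01,
                           epsilon: float = 1e-3,
                           eta: float = 0.2,
                           n_grid: int = 41) -> IdentifiabilityReport:
    """Full report: FIM rank, per-parameter profiles, combined verdict.

    Full FIM rank and an interior profile minimum for every parameter are
    both required (either alone can mislead).
    """
    v0 = float(series.burdens[0])
    initial = ((1.0 - resistant_fraction) * v0, resistant_fraction * v0)
    sm = sensitivity_matrix(estimate, series.times, initial,
                            epsilon=epsilon)
    F = fim(sm)
    rank, sv = fim_rank(F)
    profiles = {}
    for i, name in enumerate(PARAM_NAMES):
        profiles[name] = profile_likelihood(
            series, estimate, i, eta=eta, n_grid=n_grid,
            resistant_fraction=resistant_fraction)
    verdict = rank == 4 and all(pc.has_interior_minimum
                                for pc in profiles.values())
    return IdentifiabilityReport(fim=F, singular_values=sv, rank=rank,
                                 profiles=profiles, identifiable=verdict)
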