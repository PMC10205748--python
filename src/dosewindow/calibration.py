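"""Maximum-likelihood calibration of the competition model.

The observed burden V(t_n) is modelled as Poisson with the model-predicted
total burden y(t_n; p) = S(t_n) + R(t_n) as intensity, giving

    NLL(p) = sum_n [ -V(t_n) ln y(t_n; p) + y(t_n; p) + ln Gamma(V(t_n)+1) ]

minimized over p = (r, K, delta, c) by Nelder-Mead in log-parameter space
(log r, log K, log delta, log(c-1)), which enforces positivity and c > 1
without penalties. The lnGamma(V+1) term generalizes the factorial so
non-integer (real-valued) burdens are accepted; it is constant in p and
only shifts the absolute NLL.

Initial conditions are not fitted: S(0)+R(0) is anchored to the first
observation and the resistant fraction is fixed (default 1%), so exactly
the four parameters above are free — the identifiability analysis presumes
this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from ._fast import integrate_states
from .cohort import ObservedSeries
from .model import PatientParameters, TumorState

__all__ = ["FitResult", "model_mean", "negative_log_likelihood", "fit"]

_LOG_BOUND = 50.0  # reject log-parameters this far out; overflow guard


@dataclass
class FitResult:
    estimate: PatientParameters
    nll: float
    converged: bool
    n_restarts_used: int
    fixed_inputs: dict
    history: list = field(default_factory=list)  # best-so-far NLL per iterate

    def to_dict(self) -> dict:
        return {
            "estimate": dict(zip(("r", "K", "delta", "c"),
                                 self.estimate.as_array().tolist())),
            "nll": self.nll,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "fixed_inputs": self.fixed_inputs,
        }


def model_mean(params: PatientParameters, times, initial,
               dt_max: float = 0.1) -> np.ndarray:
    """Model-predicted total burden y(t_n) = S(t_n)+R(t_n) under MTD (u=1).

    ``initial`` is the state at the first time point. Raises if any mean
    is non-positive (the Poisson likelihood would be undefined).
    """
    times = np.asarray(times, dtype=float)
    if isinstance(initial, TumorState):
        S0, R0 = initial.S, initial.R
    else:
        S0, R0 = float(initial[0]), float(initial[1])
    S, R = integrate_states(S0, R0, float(times[0]), times,
                            params.r, params.K, params.delta, params.c,
                            dt_max)
    y = S + R
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("model mean non-positive or non-finite; "
                         "parameter vector rejected")
    return y


def _anchored_initial(series: ObservedSeries, resistant_fraction: float):
    v0 = float(series.burdens[0])
    return ((1.0 - resistant_fraction) * v0, resistant_fraction * v0)


def negative_log_likelihood(series: ObservedSeries,
                            params: PatientParameters,
                            resistant_fraction: float = 0.01,
                            dt_max: float = 0.1) -> float:
    """Poisson NLL of a series; +inf if the model mean is invalid."""
    initial = _anchored_initial(series, resistant_fraction)
    try:
        y = model_mean(params, series.times, initial, dt_max=dt_max)
    except ValueError:
        return np.inf
    V = series.burdens
    return float(np.sum(-V * np.log(y) + y + gammaln(V + 1.0)))


def _params_from_x(x: np.ndarray) -> PatientParameters | None:
    if np.any(np.abs(x) > _LOG_BOUND):
        return None
    r, K, delta = np.exp(x[:3])
    c = 1.0 + np.exp(x[3])
    try:
        return PatientParameters(r=r, K=K, delta=delta, c=c)
    except ValueError:
        return None


def _x_from_params(p: PatientParameters) -> np.ndarray:
    return np.array([np.log(p.r), np.log(p.K), np.log(p.delta),
                     np.log(p.c - 1.0)])


def _default_guess(series: ObservedSeries) -> PatientParameters:
    vmax = float(series.burdens.max())
    r = 0.15
    return PatientParameters(r=r, K=1.2 * vmax, delta=0.6 * r, c=2.5)


def fit(series: ObservedSeries,
        init: PatientParameters | None = None,
        n_restarts: int = 10,
        seed: int | None = 0,
        resistant_fraction: float = 0.01,
        perturbation: float = 0.5,
        xatol: float = 1e-8,
        fatol: float = 1e-8,
        maxiter: int = 4000,
        track_history: bool = False,
        dt_max: float = 0.1) -> FitResult:
    """Nelder-Mead maximum-likelihood fit with multi-start.

    The first start is ``init`` (or a data-driven heuristic); the remaining
    ``n_restarts - 1`` starts perturb it log-uniformly by up to
    ``perturbation`` (default +/-50%). Requires at least four observations
    (four free parameters).
    """
    if len(series) < 4:
        raise ValueError(f"need >= 4 observations to fit 4 parameters, "
                         f"got {len(series)}")
    if init is None:
        init = _default_guess(series)
    rng = np.random.default_rng(seed)
    x0 = _x_from_params(init)

    def objective(x):
        p = _params_from_x(x)
        if p is None:
            return np.inf
        return negative_log_likelihood(series, p,
                                       resistant_fraction=resistant_fraction,
                                       dt_max=dt_max)

    best = None
    history: list[float] = []
    n_used = 0
    for k in range(max(1, n_restarts)):
        if k == 0:
            xk = x0
        else:
            xk = x0 + rng.uniform(-np.log(1.0 + perturbation),
                                  np.log(1.0 + perturbation), size=4)
        run_history: list[float] = []

        def callback(xc):
            if track_history:
                run_history.append(objective(xc))

        res = minimize(objective, xk, method="Nelder-Mead",
                       callback=callback if track_history else None,
                       options={"xatol": xatol, "fatol": fatol,
                                "maxiter": maxiter, "maxfev": maxiter})
        n_used += 1
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
            if track_history:
                history = list(np.minimum.accumulate(run_history))
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all restarts failed to produce a finite NLL")
    estimate = _params_from_x(best.x)
    return FitResult(
        estimate=estimate,
        nll=float(best.fun),
        converged=bool(best.success),
        n_restarts_used=n_used,
        fixed_inputs={"resistant_fraction": resistant_fraction,
                      "v0_anchor": float(series.burdens[0])},
        history=history,
    )
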