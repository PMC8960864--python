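"""Least-squares calibration of the closure parameters to an annual series.

Given observed annual burn rate and human ignitions per unit forest area,
the fit adjusts a chosen subset of the behavioural closure coefficients so
the simulated series match both observations jointly. Residuals of each
series are normalized by that series' observed mean so neither dominates,
and a bounded local optimizer is restarted from multiple seeded points to
guard against local minima.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigError
from .params import CLOSURE_PARAMS, ModelParams
from .simulate import integrate

__all__ = ["ObservedSeries", "FitResult", "fit"]


@dataclass
class ObservedSeries:
    """Annual observations: year index, burn rate, human ignitions.

    Both rates are per unit forest area. At least five observations with
    strictly increasing years are required.
    """

    year: np.ndarray
    burn_rate: np.ndarray
    human_ignition: np.ndarray

    def __post_init__(self) -> None:
        self.year = np.asarray(self.year, dtype=float)
        self.burn_rate = np.asarray(self.burn_rate, dtype=float)
        self.human_ignition = np.asarray(self.human_ignition, dtype=float)
        if not (self.year.size == self.burn_rate.size == self.human_ignition.size):
            raise ConfigError("year, burn_rate, human_ignition must be equal length")
        if self.year.size < 5:
            raise ConfigError("need at least 5 observations")
        if np.any(np.diff(self.year) <= 0):
            raise ConfigError("years must be strictly increasing")
        if np.any(self.burn_rate < 0) or np.any(self.human_ignition < 0):
            raise ConfigError("observed rates must be nonnegative")
        if self.burn_rate.max() <= 0 or self.human_ignition.max() <= 0:
            raise ConfigError("degenerate observed series (all zero)")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservedSeries":
        """Read a delimited table with columns year, burn_rate, human_ignition."""
        df = pd.read_csv(path)
        missing = {"year", "burn_rate", "human_ignition"} - set(df.columns)
        if missing:
            raise ConfigError(f"observed series is missing column(s): {sorted(missing)}")
        return cls(
            year=df["year"].to_numpy(),
            burn_rate=df["burn_rate"].to_numpy(),
            human_ignition=df["human_ignition"].to_numpy(),
        )


@dataclass
class FitResult:
    """Fitted parameters and fit diagnostics."""

    params: ModelParams
    estimates: dict[str, float]
    residual_norm: float  # sum of squared normalized residuals
    rmse_burn: float  # unnormalized RMSE per series
    rmse_ignition: float
    converged: bool
    n_starts: int
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "residual_norm": self.residual_norm,
            "rmse_burn": self.rmse_burn,
            "rmse_ignition": self.rmse_ignition,
            "converged": self.converged,
            "n_starts": self.n_starts,
        }


def _simulated_series(
    params: ModelParams, years: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    horizon_steps = int(np.ceil(years[-1] / dt))
    traj = integrate(params, horizon=horizon_steps * dt, dt=dt)
    return (
        np.interp(years, traj.t, traj.B),
        np.interp(years, traj.t, traj.i_h),
    )


def _residuals(
    x: np.ndarray,
    free: list[str],
    params0: ModelParams,
    observed: ObservedSeries,
    scales: tuple[float, float],
    dt: float,
) -> np.ndarray:
    try:
        params = params0.with_updates(**dict(zip(free, x)))
        sim_b, sim_ih = _simulated_series(params, observed.year, dt)
    except (ConfigError, FloatingPointError, RuntimeError):
        return np.full(2 * observed.year.size, 1e6)
    if not (np.all(np.isfinite(sim_b)) and np.all(np.isfinite(sim_ih))):
        return np.full(2 * observed.year.size, 1e6)
    return np.concatenate(
        [(sim_b - observed.burn_rate) / scales[0], (sim_ih - observed.human_ignition) / scales[1]]
    )


def fit(
    observed: ObservedSeries,
    free: set[str] | list[str],
    bounds: dict[str, tuple[float, float]],
    params0: ModelParams | None = None,
    n_starts: int = 10,
    seed: int = 0,
    dt: float = 1.0 / 32.0,
) -> FitResult:
    """Fit the named closure parameters to the observed series.

    Parameters
    ----------
    observed : ObservedSeries
    free : set of str
        Subset of the closure-parameter names to fit; the rest stay at
        ``params0``. An empty set returns ``params0`` with its residual.
    bounds : dict
        Finite (low, high) box per free parameter.
    params0 : ModelParams
        Starting configuration (defaults to the shipped base run).
    n_starts : int
        Local searches: one from ``params0`` plus seeded uniform restarts
        within the bounds; the best endpoint wins.
    seed : int
        Seeds the restart draws; the fit is deterministic given it.

    Returns
    -------
    FitResult
        Estimates, the summed squared normalized residual, per-series RMSE,
        and a convergence flag (the best-found point is returned even on
        non-convergence).
    """
    params0 = params0 or ModelParams()
    free = sorted(free)
    extra = set(free) - CLOSURE_PARAMS
    if extra:
        raise ConfigError(
            f"can only fit closure parameters {sorted(CLOSURE_PARAMS)}; got {sorted(extra)}"
        )
    scales = (float(observed.burn_rate.mean()), float(observed.human_ignition.mean()))

    if not free:
        res = _residuals(np.empty(0), [], params0, observed, scales, dt)
        return _result(params0, [], np.empty(0), res, observed, True, 0)

    missing = set(free) - set(bounds)
    if missing:
        raise ConfigError(f"missing bounds for: {sorted(missing)}")
    lo = np.array([bounds[name][0] for name in free], dtype=float)
    hi = np.array([bounds[name][1] for name in free], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))) or np.any(lo > hi):
        raise ConfigError("bounds must be finite with low <= high")

    rng = np.random.default_rng(seed)
    x0s = [np.clip([getattr(params0, name) for name in free], lo, hi)]
    x0s += [rng.uniform(lo, hi) for _ in range(max(0, n_starts - 1))]

    best = None
    for x0 in x0s:
        sol = least_squares(
            _residuals,
            x0,
            bounds=(lo, hi),
            args=(free, params0, observed, scales, dt),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    fitted = params0.with_updates(**dict(zip(free, best.x)))
    res = _residuals(best.x, free, params0, observed, scales, dt)
    return _result(fitted, free, best.x, res, observed, bool(best.success), len(x0s), best.message)


def _result(params, free, x, res, observed, converged, n_starts, message=""):
    n = observed.year.size
    scales = (observed.burn_rate.mean(), observed.human_ignition.mean())
    rmse_b = float(np.sqrt(np.mean((res[:n] * scales[0]) ** 2)))
    rmse_ih = float(np.sqrt(np.mean((res[n:] * scales[1]) ** 2)))
    return FitResult(
        params=params,
        estimates=dict(zip(free, np.asarray(x, dtype=float))),
        residual_norm=float(np.sum(res**2)),
        rmse_burn=rmse_b,
        rmse_ignition=rmse_ih,
        converged=converged,
        n_starts=n_starts,
        message=str(message),
    )
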