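"""Vectorized integration of a parameter ensemble.

Integrates many model configurations simultaneously by broadcasting the rate
equations over NumPy arrays: each ensemble member carries its own parameter
values and initial state. Shares the exact rate code with the scalar
integrator (:mod:`firecycle.model`), so a size-1 ensemble reproduces
:func:`firecycle.simulate.integrate` to floating-point identity.

Runs whose state leaves the valid domain beyond tolerance are flagged as
diverged and carried as NaN rather than aborting the sweep.
"""

from __future__ import annotations

from types import SimpleNamespace
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .model import Instant, _rhs, instantaneous
from .params import CLOSURE_PARAMS, SIMPLEX_TOL, ModelParams, PolicyConfig

__all__ = ["make_ensemble_params", "integrate_ensemble", "EnsembleTrajectories"]

#: ModelParams fields that may be overridden per-run.
_SWEEPABLE = CLOSURE_PARAMS | {
    "tau1",
    "tau2",
    "delta1",
    "gamma_max",
    "steepness",
    "n",
    "sigma",
    "i_n",
    "s0",
    "f0",
    "v0",
    "ih0",
    "ignition_baseline",
}


def make_ensemble_params(
    base: ModelParams, overrides: Mapping[str, np.ndarray] | None = None
) -> SimpleNamespace:
    """Namespace of (scalar or per-run array) parameters with derived anchors.

    ``overrides`` maps parameter names to arrays of per-run values; all other
    fields are taken from ``base``. The derived quantities ``bbar0`` (initial
    perceived burn rate) and ``h0`` (ignition baseline) are recomputed
    per run with the same closure rules as :class:`ModelParams`.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - _SWEEPABLE
    if unknown:
        raise ConfigError(f"cannot sweep parameter(s): {sorted(unknown)}")
    ns = SimpleNamespace(
        **{
            name: np.asarray(overrides[name], dtype=float) if name in overrides
            else getattr(base, name)
            for name in _SWEEPABLE - {"ignition_baseline"}
        }
    )
    # Derived anchors, vectorized mirror of ModelParams.bbar0 / .h0.
    gamma_f0 = ns.burn_per_ignition * (ns.ih0 + ns.i_n)
    x = gamma_f0 * ns.f0
    gamma_s0 = np.where(
        np.greater(x, 0.0),
        ns.gamma_max / (1.0 + np.exp(-ns.steepness * (np.asarray(x) / ns.n - 1.0))),
        0.0,
    )
    ns.bbar0 = gamma_f0 * ns.f0 + gamma_s0 * ns.s0
    if "ignition_baseline" in overrides:
        ns.h0 = np.asarray(overrides["ignition_baseline"], dtype=float)
    else:
        # Anchored at the *base* configuration: per-run draws of the other
        # closures perturb ignition pressure away from the anchor rather
        # than re-deriving (and possibly blowing up) the multiplier.
        ns.h0 = base.h0
    ns.perception = base.perception
    return ns


class EnsembleTrajectories:
    """Recorded series of an ensemble run.

    Attributes
    ----------
    t : ndarray, shape (n_times,)
    series : dict of name -> ndarray, shape (n_times, n_runs)
        Recorded outputs (states and/or derived series).
    diverged : ndarray of bool, shape (n_runs,)
        Runs that left the valid state domain (their series are NaN from the
        point of failure on).
    """

    def __init__(self, t: np.ndarray, series: dict[str, np.ndarray], diverged: np.ndarray):
        self.t = t
        self.series = series
        self.diverged = diverged

    @property
    def n_runs(self) -> int:
        return int(self.diverged.size)


def integrate_ensemble(
    params_ns: SimpleNamespace,
    horizon: float = 20.0,
    dt: float = 1.0 / 64.0,
    policy: PolicyConfig | None = None,
    record: tuple[str, ...] = ("B", "S", "F", "V"),
) -> EnsembleTrajectories:
    """RK4-integrate every ensemble member over ``[0, horizon]``.

    ``record`` may name any of S, F, E, V, Bbar, cumB, B, I_H, gammaF,
    gammaS.
    """
    if horizon <= 0 or dt <= 0 or dt > 0.25:
        raise ConfigError("horizon must be positive and dt in (0, 0.25]")
    n_steps = int(round(horizon / dt))
    perception = getattr(params_ns, "perception", "delay")
    if perception == "delay" and np.min(params_ns.delta1) < dt:
        raise ConfigError("delay-mode perception requires delta1 >= dt for every run")

    names = [n for n in vars(params_ns) if n != "perception"]
    shape = np.broadcast_shapes(*[np.shape(getattr(params_ns, n)) for n in names])
    n_runs = int(np.prod(shape)) if shape else 1

    def full(value):
        return np.broadcast_to(np.asarray(value, dtype=float), (n_runs,)).copy()

    S = full(params_ns.s0)
    F = full(params_ns.f0)
    V = full(params_ns.v0)
    bbar0 = full(params_ns.bbar0)
    cumB = np.zeros(n_runs)
    diverged = np.zeros(n_runs, dtype=bool)

    times = np.arange(n_steps + 1) * dt
    derived = {"B": "B", "I_H": "i_h", "gammaF": "gamma_f", "gammaS": "gamma_s"}
    out = {name: np.empty((n_steps + 1, n_runs)) for name in record}

    def snapshot(k: int, y: tuple[np.ndarray, ...], t: float) -> Instant:
        inst = instantaneous(y, params_ns, policy, t)
        for name in record:
            if name in ("S", "F", "V", "Bbar", "cumB"):
                out[name][k] = y[("S", "F", "V", "Bbar", "cumB").index(name)]
            elif name == "E":
                out[name][k] = 1.0 - y[0] - y[1]
            elif name in derived:
                out[name][k] = getattr(inst, derived[name])
            else:
                raise ConfigError(f"unknown output series {name!r}")
        return inst

    # Burn-rate history for the transport-delay perception lookup.
    b_hist = np.zeros((n_steps + 1, n_runs))
    delta1 = full(params_ns.delta1)
    runs = np.arange(n_runs)

    def bbar_at(t: float) -> np.ndarray:
        tau = t - delta1
        pos = np.clip(tau, 0.0, None) / dt
        j = np.minimum(pos.astype(int), n_steps - 1)
        frac = pos - j
        val = b_hist[j, runs] * (1.0 - frac) + b_hist[j + 1, runs] * frac
        return np.where(tau <= 0.0, bbar0, val)

    def f_smooth(y_tuple, t):
        rates, _ = _rhs(y_tuple, params_ns, policy, t)
        return rates

    def f_delay(y_tuple, t):
        S, F, V, cumB = y_tuple
        rates, _ = _rhs((S, F, V, bbar_at(t), cumB), params_ns, policy, t)
        return (rates.dS, rates.dF, rates.dV, rates.dcumB)

    def axpy(y_tuple, coeff, rates):
        return tuple(yi + coeff * ri for yi, ri in zip(y_tuple, rates))

    def rk4(y, t, f):
        k1 = f(y, t)
        k2 = f(axpy(y, 0.5 * dt, k1), t + 0.5 * dt)
        k3 = f(axpy(y, 0.5 * dt, k2), t + 0.5 * dt)
        k4 = f(axpy(y, dt, k3), t + dt)
        return tuple(
            yi + (dt / 6.0) * (a + 2.0 * b + 2.0 * c + d)
            for yi, a, b, c, d in zip(y, k1, k2, k3, k4)
        )

    if perception == "smooth":
        y = (S, F, V, bbar0, cumB)
        snapshot(0, y, 0.0)
        for k in range(n_steps):
            y = rk4(y, times[k], f_smooth)
            y, diverged = _project_ensemble(y, diverged)
            snapshot(k + 1, y, times[k + 1])
    else:
        y = (S, F, V, cumB)
        inst = snapshot(0, (S, F, V, bbar0, cumB), 0.0)
        b_hist[0] = inst.B
        for k in range(n_steps):
            y = rk4(y, times[k], f_delay)
            t_next = times[k + 1]
            bbar = bbar_at(t_next)
            state5 = (y[0], y[1], y[2], bbar, y[3])
            state5, diverged = _project_ensemble(state5, diverged)
            y = (state5[0], state5[1], state5[2], state5[4])
            inst = snapshot(k + 1, state5, t_next)
            b_hist[k + 1] = np.where(diverged, 0.0, np.nan_to_num(inst.B, nan=0.0))

    for name in record:
        out[name][:, diverged] = np.nan
    return EnsembleTrajectories(t=times, series=out, diverged=diverged)


def _project_ensemble(y, diverged):
    S, F, V, Bbar, cumB = (np.array(a, dtype=float, copy=True) for a in y)
    violation = np.maximum.reduce([-S, -F, (S + F) - 1.0, -V, -Bbar])
    diverged = diverged | (violation > SIMPLEX_TOL)
    S = np.clip(S, 0.0, 1.0)
    F = np.clip(F, 0.0, 1.0 - S)
    V = np.maximum(V, 0.0)
    Bbar = np.maximum(Bbar, 0.0)
    cumB = np.maximum(cumB, 0.0)
    for arr in (S, F, V, Bbar, cumB):
        arr[diverged] = np.nan
    return (S, F, V, Bbar, cumB), diverged
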