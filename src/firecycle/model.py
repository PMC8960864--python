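"""Instantaneous rate equations of the coupled human-natural wildfire model.

Vegetation succession on a unit forest area::

    E     = 1 - F - S                         (empty area)
    dS/dt = F/tau1 - (alpha + gamma_S) S      (strong vegetation)
    dF/dt = E/tau2 + alpha S - (1/tau1 + gamma_F) F

with ``B = gamma_F F + gamma_S S`` the total burn rate, ``alpha = sigma B``
the fire-driven conversion of strong to flammable vegetation, and
``gamma_S = f(gamma_F F)`` a sigmoid: large flammable-vegetation fires
propagate into the strong stock.

The human subsystem couples through human ignition
``I_H = h0 (V/V0) max(0, 1 - s Bbar)`` (rising with settlement, suppressed by
perceived risk), through perception ``dBbar/dt = (B - Bbar)/delta1`` (a
first-order lag), and through vulnerable-property dynamics
``dV/dt = V (theta E_bt - rho)`` where development ``theta E_bt`` is
suppressed by perceived risk and demolition ``rho = rho0 + d B`` is mainly
fire-driven.

All functions accept scalars or NumPy arrays (broadcasting), which lets the
Monte-Carlo sweep integrate a whole parameter ensemble at once.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import InvalidStateError
from .params import SIMPLEX_TOL, ModelParams, PolicyConfig, SystemState

__all__ = [
    "empty_area",
    "flammable_burn_fraction",
    "strong_burn_fraction",
    "burn_rate",
    "vulnerability_rate",
    "human_ignition",
    "perception_rate",
    "property_rate",
    "derivatives",
    "Rates",
    "Instant",
]


class Rates(NamedTuple):
    """Time derivatives of the five stocks."""

    dS: float
    dF: float
    dV: float
    dBbar: float
    dcumB: float


class Instant(NamedTuple):
    """Instantaneous derived quantities at one state (policy-adjusted)."""

    E: float
    i_h: float
    gamma_f: float
    gamma_s: float
    B: float
    alpha: float


def empty_area(S, F):
    """Empty forest area ``E = 1 - F - S``.

    Raises :class:`InvalidStateError` if the vegetation stocks leave the unit
    simplex by more than floating-point tolerance.
    """
    if np.any(np.less(S, -SIMPLEX_TOL)) or np.any(np.less(F, -SIMPLEX_TOL)):
        raise InvalidStateError("negative vegetation stock")
    E = 1.0 - F - S
    if np.any(np.less(E, -SIMPLEX_TOL)):
        raise InvalidStateError("S + F exceeds the total forest area")
    return E


def flammable_burn_fraction(i_h, i_n, burn_per_ignition):
    """Fractional burning rate of flammable vegetation,
    ``gamma_F = c (I_H + I_N)`` — linear in total ignition."""
    return burn_per_ignition * (np.asarray(i_h, dtype=float) + i_n)


def strong_burn_fraction(gamma_f, F, params: ModelParams):
    """Fractional burning rate of strong vegetation.

    A sigmoid of the flammable-vegetation fire size ``gamma_F F``::

        gamma_S = gamma_max / (1 + exp(-steepness (gamma_F F / n - 1)))

    At ``gamma_F F = n`` it sits at half its ceiling; small surface fires
    barely touch the strong stock while large ones approach ``gamma_max``.
    Strong-vegetation burning is fire *propagation*: with no surface fire at
    all (``gamma_F F == 0``) there is nothing to propagate, so the residual
    sigmoid offset is gated to exactly zero — this closes the fire-free
    limit (no ignition => no burning => S recovers fully).
    """
    x = np.asarray(gamma_f, dtype=float) * np.asarray(F, dtype=float)
    # exponent clipped: RK trial states may briefly leave the domain, and
    # e^700+ would overflow without changing the saturated result
    exponent = np.clip(-params.steepness * (x / params.n - 1.0), -700.0, 700.0)
    sig = params.gamma_max / (1.0 + np.exp(exponent))
    return np.where(x > 0.0, sig, 0.0)[()]


def burn_rate(gamma_f, F, gamma_s, S):
    """Total burn rate ``B = gamma_F F + gamma_S S`` (area / yr)."""
    return gamma_f * F + gamma_s * S


def vulnerability_rate(B, sigma):
    """Conversion rate of strong to flammable vegetation, ``alpha = sigma B``."""
    return sigma * B


def human_ignition(V, Bbar, params: ModelParams):
    """Human-caused ignition level ``I_H = h0 (V/V0) max(0, 1 - s Bbar)``.

    Proportional to vulnerable property (settlement drives ignition) and
    linearly suppressed by perceived burning, floored at zero. ``h0`` is
    anchored so that the initial state yields the configured ``ih0``.
    """
    suppression = np.maximum(0.0, 1.0 - params.ignition_sensitivity * np.asarray(Bbar, dtype=float))
    return params.h0 * (np.asarray(V, dtype=float) / params.v0) * suppression


def perception_rate(B, Bbar, delta1):
    """First-order perception lag: ``dBbar/dt = (B - Bbar) / delta1``."""
    return (np.asarray(B, dtype=float) - np.asarray(Bbar, dtype=float)) / delta1


def _development_term(Bbar, params: ModelParams, policy: PolicyConfig | None, t):
    """Fractional development rate theta * E_bt, or the P1 cap."""
    if policy is not None and policy.p1 and t >= policy.start_time:
        return policy.dev_rate_cap
    return params.dev_propensity * np.maximum(
        0.0, 1.0 - params.dev_sensitivity * np.asarray(Bbar, dtype=float)
    )


def property_rate(V, Bbar, B, params: ModelParams, policy: PolicyConfig | None = None, t: float = 0.0):
    """Vulnerable-property dynamics ``dV/dt = V (theta E_bt - rho)``.

    Development is proportional to the current stock and suppressed by
    perceived risk; demolition ``rho = rho0 + d B`` is mainly fire-driven.
    V = 0 is absorbing.
    """
    dev = _development_term(Bbar, params, policy, t)
    rho = params.demolition_base + params.demolition_fire * np.asarray(B, dtype=float)
    return np.asarray(V, dtype=float) * (dev - rho)


def instantaneous(state_tuple, params, policy: PolicyConfig | None, t):
    """Derived quantities (policy-adjusted) at one state.

    ``state_tuple`` is ``(S, F, V, Bbar, cumB)`` of scalars or arrays;
    ``params`` is a :class:`ModelParams` or any namespace exposing the same
    attributes (possibly array-valued, for ensemble integration).
    """
    S, F, V, Bbar, _ = state_tuple
    E = 1.0 - S - F
    i_h = human_ignition(V, Bbar, params)
    gamma_f = flammable_burn_fraction(i_h, params.i_n, params.burn_per_ignition)
    gamma_s = strong_burn_fraction(gamma_f, F, params)
    if policy is not None and policy.p3 and t >= policy.start_time:
        gamma_s = gamma_s * policy.firefight_factor
    B = burn_rate(gamma_f, F, gamma_s, S)
    alpha = vulnerability_rate(B, params.sigma)
    return Instant(E=E, i_h=i_h, gamma_f=gamma_f, gamma_s=gamma_s, B=B, alpha=alpha)


def _rhs(state_tuple, params, policy: PolicyConfig | None, t):
    """Full rate vector (policy-aware) plus the derived instant."""
    S, F, V, Bbar, _ = state_tuple
    inst = instantaneous(state_tuple, params, policy, t)
    dS = F / params.tau1 - (inst.alpha + inst.gamma_s) * S
    dF = inst.E / params.tau2 + inst.alpha * S - (1.0 / params.tau1 + inst.gamma_f) * F
    if policy is not None and t >= policy.start_time:
        if policy.p2:
            dF = dF - policy.omega * F  # prescribed burning: F -> empty
        if policy.p4:
            clearcut = policy.vartheta * S
            dS = dS - clearcut
            if not policy.p4_to_empty:
                dF = dF + clearcut  # clear cutting: S -> flammable
    dV = property_rate(V, Bbar, inst.B, params, policy, t)
    dBbar = perception_rate(inst.B, Bbar, params.delta1)
    return Rates(dS=dS, dF=dF, dV=dV, dBbar=dBbar, dcumB=inst.B), inst


def derivatives(
    state: SystemState,
    params: ModelParams,
    policy: PolicyConfig | None = None,
    t: float = 0.0,
) -> Rates:
    """Rate vector of the full model at ``state`` and time ``t``.

    Active policy levers are applied (P1/P3 reshape the development and
    strong-burn terms, P2/P4 add conserving flows). The implied
    ``dE/dt = -dS/dt - dF/dt`` exactly, so S + F + E = 1 is conserved.
    """
    state.validate()
    if t < 0:
        raise InvalidStateError(f"time must be >= 0, got {t}")
    rates, _ = _rhs(state.as_tuple(), params, policy, t)
    return rates
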