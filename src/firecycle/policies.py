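"""Policy levers and their application to the model's rate vector.

Four levers, freely combinable and switched on as a step at the configured
start year:

* **P1 — limit property development**: the fractional development rate of
  vulnerable property is fixed at ``dev_rate_cap`` (default 1 %/yr),
  replacing the perception-driven development term.
* **P2 — prescribed burning**: a controlled outflow ``omega * F`` from
  flammable vegetation to empty area (default 0.2/yr).
* **P3 — effective firefighting**: the fractional burning rate of strong
  vegetation is scaled to ``firefight_factor`` of its sigmoid value
  (default 10 %), limiting fire penetration into the strong stock.
* **P4 — clear cutting**: an outflow ``vartheta * S`` removed from strong
  vegetation (default 0.2/yr). By default the cleared area becomes empty
  ground that regrows young flammable vegetation; ``p4_to_empty=False``
  routes the outflow directly into the flammable stock instead.

Every lever conserves total area: dS/dt + dF/dt + dE/dt = 0 under any
combination.
"""

from __future__ import annotations

from .model import Rates, _rhs
from .params import ModelParams, PolicyConfig, SystemState

__all__ = ["PolicyConfig", "apply_policies"]


def apply_policies(
    rates: Rates,
    state: SystemState,
    params: ModelParams,
    policy: PolicyConfig | None,
    t: float,
) -> Rates:
    """Return the rate vector with active policy levers applied.

    ``rates`` is the no-policy rate vector at ``state``; before the policy
    start time (or with no lever active) it is returned unchanged. The
    additive levers (P2, P4) shift flows relative to ``rates``; P1 and P3
    reshape the development and strong-burn terms, so the affected rates are
    re-derived from ``state``.
    """
    if policy is None or not policy.active_at(t):
        return rates
    state.validate()
    out, _ = _rhs(state.as_tuple(), params, policy, t)
    return out
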