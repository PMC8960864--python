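# firecycle

**Wildfire as a coupled human–natural system: a system-dynamics simulator.**

Annual burned area in many fire-prone regions does not grow smoothly — it
cycles, with peaks that keep getting higher. `firecycle` implements a
compact stock-flow model in which those cycles emerge from the coupling
between a natural subsystem (vegetation succession and fire) and a human
subsystem (settlement in the wildland–urban interface and risk
perception), rather than from external forcing. It is aimed at
ecological-modelling and natural-hazard-policy researchers who want a
transparent, fully reproducible sandbox for studying fire–human feedback
and for comparing containment policies singly and in combination.

## The model

A unit forest area is split into strong vegetation `S`, flammable
vegetation `F`, and empty ground `E = 1 − S − F`:

```
dS/dt = F/τ1 − (α + γS)·S
dF/dt = E/τ2 + α·S − (1/τ1 + γF)·F
B     = γF·F + γS·S                      (total burn rate)
```

Flammable vegetation burns in proportion to total ignition,
`γF = c·(I_H + I_N)`; fire penetrates the strong stock through a sigmoid
switch `γS = γmax/(1 + exp(−κ(γF F/n − 1)))`; burning makes surviving
strong vegetation more vulnerable, `α = σB`. The human side closes the
loop: vulnerable property `V` develops when perceived risk is low and is
demolished by fire, `dV/dt = V(θ·max(0, 1 − k·B̄) − ρ0 − d·B)`, and human
ignition rises with settlement but falls with perceived risk,
`I_H = h0 (V/V0) max(0, 1 − s·B̄)`. Perceived burning `B̄` is the actual
burn rate delayed by `δ1` years — the delayed negative feedback
(complacency) that, together with the sigmoid fire switch, generates
fire cycles of growing amplitude.

Four policy levers can be imposed at any year and combined freely:
**P1** caps property development at 1 %/yr, **P2** prescribed-burns the
flammable stock (`ω·F` to empty area), **P3** cuts fire penetration into
strong vegetation to 10 % (firefighting), **P4** clear-cuts strong
vegetation into the flammable stock (`ϑ·S`). See `docs/methods.md` for
the complete formulation, parameter table and numerical choices.

## Worked example

```python
from firecycle import ModelParams, PolicyConfig, integrate, reduction_percent

params = ModelParams()                     # the calibrated base configuration
base = integrate(params, horizon=20.0)     # 20-year base run

# Prescribed burning + firefighting, imposed at year 5:
policy = PolicyConfig.combo("p2", "p3", start_time=5.0)
treated = integrate(params, policy=policy, horizon=20.0)

print(f"burned area years 10-20, base:    {base.cumB[-1] - base.at(10.0).cumB:.3f}")
print(f"reduction vs base:                {reduction_percent(base, treated):.1f}%")
```

```
burned area years 10-20, base:    0.892
reduction vs base:                10.3%
```

The first number is the burned area (in units of the total forest area)
accumulated over the evaluation decade of the untreated run; the second
is the percent reduction achieved by the P2+P3 combination — note it is
*less* than the sum of the two single-policy effects, because both levers
act on the vegetation side only: the burn relief lowers perceived risk,
which rebuilds ignition pressure and property development until much of
the gain is eaten back. Pairing a vegetation-side lever with the
human-side lever P1 instead yields far more than the sum of its parts.

The same experiments are available from the shell:

```sh
firecycle simulate --horizon 20 --p2 --p3 --out-dir runs/p2p3
firecycle policy-matrix --out-dir runs/matrix      # base, 4 singles, 6 pairs, all four
firecycle coupling --delays 0.5,1,2,100 --out-dir runs/coupling
firecycle sensitivity --runs 2000 --seed 1 --out-dir runs/mc
firecycle calibrate observations.csv --free burn_per_ignition,ignition_sensitivity
```

Every command writes its numeric results as CSV/JSON plus an
`effective_config.yaml` from which the run can be reproduced exactly.

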