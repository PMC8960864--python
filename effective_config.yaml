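params:
  tau1: 2.0
  tau2: 10.0
  delta1: 1.0
  perception: delay
  gamma_max: 0.8
  steepness: 5.0
  n: 0.1
  sigma: 0.05
  i_n: 0.5
  burn_per_ignition: 0.3661
  ignition_sensitivity: 2.3496
  dev_propensity: 3.0
  dev_sensitivity: 11.8
  demolition_base: 0.08
  demolition_fire: 0.0
  ignition_baseline: null
  s0: 0.5
  f0: 0.4
  v0: 0.4
  ih0: 0.3
policy:
  p1: false
  p2: false
  p3: false
  p4: false
  start_time: 5.0
  dev_rate_cap: 0.01
  omega: 0.2
  firefight_factor: 0.1
  vartheta: 0.2
  p4_to_empty: true
integrator:
  dt: 0.015625
  horizon: -5.0
  method: rk4
seed: 0
output_dir: .
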