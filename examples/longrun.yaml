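# 100-year base-run preset: checks that the fire cycles do not fade over a
# longer horizon. Run with:
#   firecycle simulate --config examples/longrun.yaml --out-dir runs/longrun
integrator:
  horizon: 100.0
  dt: 0.015625
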