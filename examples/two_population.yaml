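# Desk-scale self-organization of the two-population network:
# 100 neurons (80 excitatory / 20 inhibitory), growth rates x10,
# 500 biological seconds. See README for the expected trajectory.
model: two_population
scale: 0.1
nu_scale: 10.0
schedule:
  t_total: 500000.0   # ms
  dt: 0.1
  structural_interval: 10.0
  seed: 1
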