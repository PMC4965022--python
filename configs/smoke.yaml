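# Minimal fast scenario for pipeline smoke tests and CLI determinism checks:
# small coarse phantom, short 18-day horizon.
phantom:
  breast_radius: 0.05
  slab_depth: 0.015
  target_edge_length: 0.011
  fibro_fraction: 0.25

resection:
  axis_point: [0.012, 0.0, 0.008]
  axis_direction: [0.0, 1.0, 0.0]
  radius: 0.016

schedule:
  t_end_days: 18.0

mechanics:
  formulation: anp
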