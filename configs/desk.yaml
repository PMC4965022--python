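# Desk-scale study preset: coarse synthetic phantom, full 90-day healing
# horizon.  Identical to the packaged defaults; stated explicitly here so the
# scenario is self-documenting.
phantom:
  breast_radius: 0.06
  slab_depth: 0.02
  target_edge_length: 0.009
  fibro_fraction: 0.25

resection:
  axis_point: [0.02, 0.0, 0.015]
  axis_direction: [0.0, 1.0, 0.0]
  radius: 0.015

schedule:
  dt_mech_days: 6.0
  t_end_days: 90.0

mechanics:
  formulation: anp

heal:
  gravity: none
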