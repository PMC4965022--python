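# Unloaded-configuration round-trip scenario: small phantom with stiffer
# (fibrotic-range) tissue so the gravity sag is a few millimetres and the
# fixed-point inverse iteration contracts quickly.
phantom:
  breast_radius: 0.045
  slab_depth: 0.015
  target_edge_length: 0.011
  fibro_fraction: 0.25

materials:
  adipose:        {c1: 2000.0, c2: 500.0,  kappa: 2.0e+5, rho0: 960.0}
  fibroglandular: {c1: 4000.0, c2: 1000.0, kappa: 2.0e+5, rho0: 1040.0}
  wound:          {c1: 2500.0, c2: 600.0,  kappa: 2.0e+5, rho0: 1000.0}

mechanics:
  formulation: penalty
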