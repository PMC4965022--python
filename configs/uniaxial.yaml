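# Uniaxial-stretch verification material: Mooney-Rivlin block in the
# near-incompressible penalty limit kappa/c1 = 1e4.
materials:
  adipose:        {c1: 100.0, c2: 25.0, kappa: 1.0e+6, rho0: 1000.0}
  fibroglandular: {c1: 100.0, c2: 25.0, kappa: 1.0e+6, rho0: 1000.0}
  wound:          {c1: 100.0, c2: 25.0, kappa: 1.0e+6, rho0: 1000.0}
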