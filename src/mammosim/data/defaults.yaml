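# Default parameter set of the breast-surgery healing simulator.
# All values SI unless the key name says otherwise.  The biochemical rates
# follow the epidermal-healing and angiogenesis modelling literature in
# order of magnitude and were calibrated once, as a set, so that a
# desk-scale phantom lumpectomy recovers to homeostasis with the clinically
# expected course: slow inflammatory onset, pronounced proliferative
# contraction in the second week, plateau by about one month.

biology:
  D_eta: 3.0e-12        # cell random motility, m^2/s
  D_sigma: 1.0e-10      # mitosis growth-factor diffusivity, m^2/s
  D_xi: 2.0e-9          # oxygen diffusivity in tissue, m^2/s
  D_mu: 5.0e-10         # MDGF diffusivity, m^2/s
  k_sigma: 3.2e-20      # cell production rate, m^3/cell/s
  eta0: 1.0e+14          # reference cell density, cell/m^3 (1e+5 per mm^3)
  h0: 10.0              # inhibitor-mode mitosis parameter (S(0) = h0)
  h1: 0.3               # activator amplitude; S(sigma0) = h1 + h2 = 1
  h2: 0.7               # activator offset (mitosis floor at zero chemical)
  ell_eta: 1.0e-18      # growth-factor production by cells, units m^3/cell/s
  ell: 1.0e-4           # growth-factor decay, 1/s  -> sigma0 = 1.0 unit
  beta: 5.0e-10         # capillary growth rate, m/s
  upsilon0: 1.0e+4       # reference capillary density, 1/m
  mu0: 1.0              # MDGF reference concentration, units
  lam: 2.0e-4           # oxygen consumption, 1/s
  phi_xi: 2.0e-5        # MDGF release under hypoxia, units/s (steady ~10 mu0)
  phi: 2.0e-7           # MDGF decay, 1/s (~2 month persistence: the angiogenic
                        # stimulus must outlast the hypoxic phase or capillary
                        # regrowth stalls below its carrying capacity
  xi_hat: 0.9           # oxygen threshold for MDGF release
  xi_tilde: 0.5         # oxygen threshold for full mitosis rate
  mitosis_mode: activator
  eta_init_wound: 0.15      # initial wound cell density, fraction of eta0
  upsilon_init_wound: 0.05  # initial wound capillary density, fraction of upsilon0
  xi_init_wound: 0.0        # initial wound oxygen level

materials:
  adipose:        {c1: 200.0,  c2: 50.0,  kappa: 5.0e+5, rho0: 960.0}
  fibroglandular: {c1: 400.0,  c2: 100.0, kappa: 5.0e+5, rho0: 1040.0}
  wound:          {c1: 250.0,  c2: 60.0,  kappa: 5.0e+5, rho0: 1000.0}
  skin:           {alpha: 2000.0, beta: 4.0, c2: -4000.0, rho0: 1100.0}
  active:         {tau_f: 3.0e-10, alpha_f: 1.0, eta0_f: 1.0e+14, wound_only: true}
  damage_volumetric: false

schedule:
  dt_bio: 17.28         # s, fine-mesh reference step
  dt_mech_days: 6.0
  t_end_days: 90.0
  cfl_safety: 0.5
  scale: 200.0          # desk-scale cap: dt_bio <= 17.28 * scale

phantom:
  breast_radius: 0.06       # m
  slab_depth: 0.02          # m
  target_edge_length: 0.009 # m
  fibro_fraction: 0.25
  jitter: 0.01
  seed: 0

resection:
  axis_point: [0.02, 0.0, 0.015]
  axis_direction: [0.0, 1.0, 0.0]   # perpendicular to the chest wall
  radius: 0.015                     # m

mesh:
  scale: 1.0                 # file length unit -> metres
  skin_thickness: 0.0015     # m

mechanics:
  formulation: anp           # 'penalty' (condensed u/p) or 'anp'
  include_skin: true
  gravity_magnitude: 9.81

heal:
  gravity: none              # pose during the healing stage

pose:
  gravity: upright
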