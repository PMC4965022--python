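# mammosim

Multiscale mechano-biological finite-element simulation of breast-conserving
surgery (lumpectomy): coupled wound healing, angiogenesis and soft-tissue
mechanics, wrapped in the surgical planning workflow — recover the
gravity-free breast shape, pose it, mark a cylindrical resection, simulate
weeks of healing-driven wound contraction, and compare the predicted skin
surface against a follow-up acquisition.

It is intended for computational biomechanics researchers prototyping
surgical-outcome models: no patient data is required — a synthetic breast
phantom (hemisphere of adipose + fibroglandular tissue on a chest-wall slab,
with a 1.5 mm skin membrane) stands in for image-derived anatomy, and
standard Gmsh MSH meshes can be used instead.

## The model

**Healing biology.** Five nodal fields on a fixed tetrahedral mesh — cell
density η, a mitosis-regulating growth factor ς, capillary density υ,
normalised oxygen level ξ and the macrophage-derived growth factor μ —
evolve by reaction–diffusion kinetics:

    η̇ = D_η ∇²η + K(ξ) S(ς)(2η₀η − η²) − kη
    ς̇ = D_ς ∇²ς + ℓ_η η − ℓς
    υ̇ = β H(μ)(υ₀υ − υ²)
    ξ̇ = D_ξ ∇²ξ + λ_υ υ − λξ
    μ̇ = D_μ ∇²μ + φ_ξ Q(ξ) − φμ

Hypoxia in the resected region releases MDGF (`Q`), which drives logistic
capillary regrowth (`H`), restoring oxygen and thereby the chemically
modulated (`S`), oxygen-gated (`K`) logistic recovery of the cell
population. Healthy tissue sits at an exact homeostatic fixed point
(η₀, ς₀, υ₀, 1, 0). Discretisation: linear tetrahedra, lumped mass,
zero-flux boundaries, explicit (forward-Euler) stepping under the CFL bound.

**Tissue mechanics.** Quasi-static Total-Lagrangian equilibrium with
quasi-incompressible Mooney-Rivlin tissue, a Veronda-Westmann skin membrane,
and two wound-specific terms driven by the shared cell density: a damage
variable ζ = 1 − η/η₀ that scales the isochoric strain energy by (1 − ζ),
and an isotropic active fibroblast traction S_active = τ_f (α_f η/η₀) η₀,f I.
Volumetric locking of linear tetrahedra is relieved by an
average-nodal-pressure projection (the element-penalty form, equivalent to
the condensed u/p element, is also available). Newton iteration with
complex-step-consistent tangents, incremental loading and line search.

**Coupling.** Biology advances in second-to-hour explicit steps; mechanics
is re-solved every 6 simulated days from the same reference configuration.
Only η flows into the mechanics (no mechano-sensing feedback). The deformed
wound volume over time is the headline output.

See `docs/methods.md` for assumptions, parameter rationale and limitations.

## Worked example

```sh
mammosim demo -c configs/desk.yaml -o out_desk --seed 1
```

runs the full desk-scale study — a ~2,000-node phantom, a 15 mm-radius
cylindrical lumpectomy, 90 days of healing — and prints

```
demo: wound 44848 mm^3 (92.2% of initial); wound means eta=1.000
upsilon=1.000 xi=1.000; max rate day 12, plateau day 24
```

i.e. the excised region has contracted to 92.2% of its immediate
post-operative volume; the cell, capillary and oxygen fields in the
recovered wound have returned to their healthy reference values; the
fastest contraction happened around day 12 (the proliferative phase) and
the breast shape was effectively final from day 24. `out_desk/` contains
the volume/species trajectory (`trajectory.csv`) and a VTU snapshot series
for ParaView.

The individual pipeline stages are also exposed (`mammosim phantom`,
`resect`, `unload`, `pose`, `heal`, `evaluate`); library users can drive
everything from Python:

```python
from mammosim import (generate_phantom, mark_resection, run_coupled,
                      load_config)

cfg = load_config("configs/desk.yaml")
mesh = mark_resection(cfg.make_phantom(seed=1), cfg.resection)
traj = run_coupled(mesh, cfg.bio, cfg.materials, cfg.schedule,
                   formulation="anp")
print(traj.table[["day", "wound_volume_mm3", "wound_mean_eta"]])
```

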