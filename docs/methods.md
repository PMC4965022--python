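# Methods

`mammosim` simulates the mechano-biological course of breast-conserving
surgery: a lumpectomy cavity is marked in a breast model, the surrounding
tissue heals over weeks, and the healing biology drives a mechanical
contraction of the operated region that reshapes the breast. This note
documents the models, their discretisation, the parameter choices and the
limits of what the synthetic studies can show.

## Wound healing and angiogenesis

Five coupled fields live on the nodes of a fixed (Lagrangian) tetrahedral
mesh:

| field | meaning | units |
|---|---|---|
| η  | tissue cell density (fibroblasts etc.) | cell·m⁻³ |
| ς  | mitosis-regulating growth factor | arbitrary |
| υ  | capillary (microvessel) density | m⁻¹ |
| ξ  | normalised oxygen/nutrient level | – |
| μ  | macrophage-derived growth factor (MDGF) | arbitrary |

The kinetics are

    η̇ = D_η ∇²η + K(ξ) S(ς) (2η₀η − η²) − kη
    ς̇ = D_ς ∇²ς + ℓ_η η − ℓς
    υ̇ = β H(μ) (υ₀υ − υ²)                    (no spatial transport)
    ξ̇ = D_ξ ∇²ξ + λ_υ υ − λξ
    μ̇ = D_μ ∇²μ + φ_ξ Q(ξ) − φμ

with `S` the chemical mitosis modulation (activator form
`2h₁ς̄ς/(ς̄²+ς²)+h₂` by default; the classical inhibitor law is available),
`H(μ)=3μ/(2μ₀+μ)` the angiogenic response, `Q = 1−ξ/ξ̂` the hypoxic MDGF
release (wound only, below the threshold ξ̂) and `K` the oxygen gating of
cell production (linear below ξ̃, saturated above).

**Homeostasis constraints.** Healthy tissue must sit exactly at
(η₀, ς₀, υ₀, 1, 0). This forces `ς₀ = ℓ_η η₀/ℓ`, `k = k_ς S(ς₀) η₀` and
`λ_υ = λ/υ₀`; the last two are *derived* at parameter construction and
user-supplied inconsistent values are overridden (logged). Without this the
"undamaged" region drifts, contradicting its boundary-condition role.

**Initial conditions.** The healthy region (and the wound/healthy interface
nodes) start at homeostasis with ς = μ = 0 everywhere. Nodes whose incident
elements are all wound-labelled start at small seed fractions of the
references (defaults: η 0.15 η₀, υ 0.05 υ₀, ξ = 0). Exact zeros would make
the logistic cell and capillary kinetics unable to regrow in the wound
interior — the capillary equation has no transport term at all — whereas the
freshly operated cavity is in reality immediately infiltrated by
inflammatory and stromal cells. The seed fractions are therefore part of the
model, exposed in the parameter file.

**Two structural timing facts** discovered while assembling the default
parameter set, both documented because they shape the defaults:

* MDGF production switches off once ξ ≥ ξ̂, so with fast MDGF decay the
  capillary logistic freezes below υ₀ (≈0.95 υ₀ was observed). The default
  MDGF decay is slow (φ = 2×10⁻⁷ s⁻¹, ≈2-month persistence) so the
  angiogenic stimulus outlasts the hypoxic phase and υ completes its
  recovery to υ₀.
* The recovery course — slow inflammatory onset, steep proliferative phase
  in the second week, plateau by about a month — is governed by the chain
  seed → MDGF rise → capillary logistic (rate βH υ₀) → oxygen → cell
  logistic (rate ≈ k). The defaults were calibrated once, as a set, to put
  the fastest contraction in the second week and the plateau near one month
  on the desk-scale phantom; they sit inside the ranges used by the
  epidermal-healing and angiogenesis modelling literature.

**Discretisation.** Linear (P1) tetrahedra, Galerkin stiffness, row-sum
lumped mass, zero-flux natural boundary conditions (the wound is interior,
so the outer boundary never sees gradients), nodal source evaluation, and
forward-Euler time stepping under the diffusive stability bound
`dt ≤ safety · min_e h_min²/(6 D_max)`. On the coarse desk meshes this bound
is a few thousand seconds; the driver picks the largest stable step that
divides the mechanics window exactly (the fine-mesh reference step is
17.28 s). A note on pointwise accuracy: on the asymmetric Kuhn lattice the
*nodal* operator M⁻¹K is not pointwise consistent at every node for general
smooth fields (a standard supraconvergence situation); the solution-level
behaviour — Dirichlet energies, Neumann eigenvalues, mass conservation,
travelling-front speeds — is what the tests pin down.

## Soft-tissue mechanics

Quasi-static Total-Lagrangian equilibrium `∇·(F S) + ρ₀ b = 0` with
Newton iteration, incremental loading with automatic cutbacks, and a
backtracking line search. Bulk tissue is quasi-incompressible Mooney-Rivlin,

    W = (1−ζ)[c₁(Ī₁−3) + c₂(Ī₂−3)] + κ/2 (J−1)²,

where the damage (integrity-loss) variable ζ = 1 − η/η₀, clamped to
[0, 1−10⁻³] and forced to zero outside the wound, scales only the isochoric
part: the volumetric penalty is kept intact so the fluid-filled cavity stays
quasi-incompressible. (A switch scales the κ term too, for comparison.)
The wound additionally carries an isotropic active fibroblast traction
`S_active = τ_f (α_f η/η₀) η₀,f I`, applied in wound-labelled elements only —
applying it in healthy tissue, where η = η₀, would contract the whole
breast. Skin is a Veronda-Westmann membrane
(`α[e^{β(Ĩ₁−3)}−1] + c₂(Ĩ₂−3)`, incompressible through the 1.5 mm
thickness) on the skin boundary patch.

**Differentiation strategy.** The 2nd Piola-Kirchhoff stress is coded
analytically; the consistent tangent ∂P/∂F is obtained by complex-step
differentiation of the stress (machine-precision, no hand-derived
elasticity tensors to get wrong). Membrane forces are the complex-step
gradient of the element energy; their tangent uses symmetric finite
differences. Tests verify residual/tangent consistency to 10⁻⁵ and better.

**Incompressibility and element technology.** For constant-strain P1
tetrahedra the classical mixed u/p element with element-wise constant
pressure condenses *exactly* to the displacement form with the volumetric
penalty — that is the `penalty` formulation. Because the element-wise
constraint makes linear tetrahedra lock volumetrically in inhomogeneous or
bending-dominated states, the production default is `anp`: an
average-nodal-pressure projection in which the volumetric energy is
`Σ_a κ_a/2 (J̄_a−1)² V_a` with J̄ₐ the volume-weighted Jacobian average over
the elements around node a. Its tangent includes the exact `d²J/dF²`
curvature term, so Newton stays quadratic. Both formulations coincide for
homogeneous deformation (tested); a cantilever test shows the penalty form
locking at κ/c₁ = 10⁴ while `anp` does not.

**Element density rule for the active stress.** ζ uses the element *mean*
of nodal η. The traction uses the element *minimum*: a boundary element
straddling the wound interface contains freshly damaged tissue and its
fibroblast traction is limited by the damaged side. On coarse meshes the
mean rule would hand interface elements more than half the peak traction at
the instant of surgery, contracting the wound before any healing has
happened — a pure discretisation artifact that vanishes under refinement.
The mean rule remains available as an option.

**Boundary conditions.** Chest-wall patch fixed, superior/inferior clipping
planes constrained to u_Z = 0, skin and lateral planes traction-free.
Gravity enters as ρ₀b with pose presets (prone +Y, supine −Y, upright −Z in
the package's X-lateral / Y-anterior / Z-cranial frame).

## Coupling

Biology and mechanics are alternated in a partitioned loop: the explicit
reaction-diffusion solver advances one mechanics window (default 6 days) on
the fixed reference mesh, the cell density is mapped to ζ and the active
traction, and the quasi-static equilibrium is re-solved from the reference
configuration (warm-started from the previous window). Only η flows from
biology to mechanics; there is no mechano-sensing feedback, so the biology
trajectory is identical with or without the mechanics solves (tested). The
wound volume is reported from deformed element volumes.

## Surgical pipeline

* **Phantom.** A hemisphere (breast, radius 0.06 m) on a slab (chest wall,
  0.02 m) meshed by clipping a structured Kuhn (6-tets-per-cube) lattice to
  the solid by element-centroid membership, with an inner half-ellipsoidal
  fibroglandular core sized to a target volume fraction and a small seeded
  jitter on interior nodes. The curved surface is resolved at the grid
  spacing (a staircase); volumes converge properly, and patch areas are
  grid-limit quantities that stabilise under refinement. The phantom stands
  in for image-derived anatomy; it has no ductal structures, no Cooper's
  ligaments, and its skin is a closed structured surface.
* **Resection.** The excision is a cylinder perpendicular to the chest wall
  running from skin to fascia; every tetrahedron whose centroid falls inside
  is relabelled wound (retained, not deleted — the damage field handles the
  mechanics). No skin is resected.
* **Unloading.** Imaged geometry is a gravity-loaded equilibrium; the
  reference configuration is recovered by Sellier fixed-point iteration
  (X ← X − (x(X) − x*)), tolerance 10⁻⁴ m, with an update-damping guard
  against element inversion. Forward solves then pose the unloaded mesh
  prone/supine/upright.
* **Evaluation.** Point-to-point ICP (nearest-neighbour correspondences,
  Kabsch update) aligns the predicted and acquired skin surfaces; exact
  point-to-triangle distances (vectorised Voronoi-region closest points)
  give per-vertex errors, summarised by mean, SD and the 50th/90th/95th
  percentiles (linear interpolation between order statistics). The distance
  is asymmetric (simulation → follow-up) by default.

## Default study (desk preset)

`configs/desk.yaml`: phantom with ~2,000 nodes (9 mm edges), a 15 mm-radius
cylindrical lumpectomy in the upper-outer quadrant, 90 days of healing in
15 six-day mechanics windows, gravity off during the healing stage (at
κ/c₁ ≥ 2×10³ gravity changes volumes by <0.3% while tripling solver cost;
the posing commands exercise gravity). With the default parameters the
wound-averaged normalised η, υ, ξ end at 1.000/0.9998/0.9998, the wound
contracts to ≈92% of its initial volume with the fastest contraction at
day 12 and the volume within 1% of its plateau from day 24.

Problem sizes used by the test-suite oracles (chosen so each check isolates
one mechanism): well-mixed kinetics on an 8-node box against an
independently coded scalar forward-Euler integration; the capillary
logistic against its closed form under clamped H; a 300-cell quasi-1D bar
for the Fisher-KPP front speed `2√(D_η r)` measured late in the run (pulled
fronts carry an O(1/t) speed transient); a 2×2×2-element block for the
uniaxial Mooney-Rivlin closed form at κ/c₁ = 10⁴; small phantoms for the
unloading round-trip.

## Known limitations

* The phantom's staircase surface concentrates stress locally; fine for
  volume-level statistics, not for skin-stress maps.
* Linear tetrahedra with ANP relieve volumetric locking but are still
  low-order; displacement fields near the wound edge are resolved only to
  the element size.
* The capillary equation has no spatial transport, so revascularisation
  timing is set by the seed fraction and MDGF kinetics rather than by
  capillary-front ingrowth.
* Contraction magnitude and timing are parameter-sensitive by construction;
  the defaults are one calibrated, documented operating point, not a
  patient-specific fit. Passing the synthetic studies shows internal
  consistency of the coupled model, not clinical accuracy.
* No radiotherapy/chemotherapy effects, no contact with imaging hardware,
  no viscoelasticity or anisotropy.
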