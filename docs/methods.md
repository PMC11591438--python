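# Methods

## Problem and model

Blood-contacting surfaces of cardiovascular devices (mechanical valve
leaflets, VAD cannulae) see supraphysiological wall shear stress (WSS),
often hundreds of dyn/cm², which strips endothelial cells (ECs) and leaves a
thrombogenic artificial surface.  Cutting microtrenches into the surface
creates recirculating pockets whose WSS is low enough for an EC monolayer to
survive.  This package models that situation in 2D:

* **Flow.**  Steady, incompressible, laminar flow of whole blood treated as
  a Newtonian fluid (μ = 3.5 cP, ρ = 1050 kg/m³) through a parallel-plate
  channel of clear height H = 0.508 mm whose floor carries a row of
  trenches.  The flow regime of interest (Re ≈ 200 based on H) justifies
  the laminar assumption; a guard refuses Re > 2000.
* **Geometry.**  Vertical trenches (depth h, width w, partitions d) or
  trapezoidal trenches whose sidewalls lean by a draft angle α from
  vertical, so the opening at the floor plane is w + 2 h tan α.  The
  included opening angle is θ = 2α; a "θ = 90°" trench has 45° walls.
  Adjacent trapezoids with d = 0 share a knife-edge apex.
* **Objective.**  Every point of the wetted floor contributes the
  floor-plane projection |dx| of its surface element; the coverage
  objective f is the projected fraction whose WSS magnitude lies strictly
  inside the viability band 10 < τ < 50 dyn/cm².  Vertical walls project to
  zero; a trapezoidal sidewall contributes h tan α.  f is evaluated over
  the patterned region only (first leading edge to last trailing edge) —
  including the entrance/exit flats would dilute f by an arbitrary length
  of flat run.  Band classification is strict at both thresholds.  WSS
  magnitude is used, so recirculation sign changes do not create artificial
  band exits.
* **Deposition.**  A deliberately reduced single-species model of activated
  platelets: advection–diffusion through the frozen steady flow with a
  first-order wall sink J = k·c on coated segments.  The coating contrast —
  reactive collagen vs a quiescent endothelial lining — is carried entirely
  by k.  This captures what full multi-constituent thrombosis models express
  by modulating the activated-platelet wall reaction rate on EC-covered
  surfaces, without the agonist cascade (thrombin/ADP/TxA₂ chemistry,
  activation kinetics and thrombus-growth feedback are out of scope).

## Discretization

* **Mesh.**  Block-structured, body-fitted quadrilaterals: one rectangular
  block over the clear channel and one ruled block per trench whose lateral
  edges follow the sidewalls exactly (no staircase approximation — sidewall
  WSS is part of the objective).  Spacings grade geometrically (default
  ratio 1.35) from a wall-adjacent spacing of `H/ny_clear/2.5` — further
  refined to h/3 when a trench is smaller than the base spacing, so 10 µm
  grooves remain resolved — up to ~2× the base size in the far field.
  Named resolutions: `sweep` (optimization), `coarse` (default), `medium`,
  `fine` (≈1.5× and 2× linear refinements of coarse).
  A validity guard refuses designs whose opening would be sampled coarser
  than 12× the base spacing after the cell-count caps (e.g. α near 90° with
  h = 3 mm implies a 169 mm opening); the optimizer records such designs as
  failed evaluations with f = 0.
* **Flow solver.**  Q2/Q1 Taylor–Hood mixed finite elements (inf-sup
  stable; no pressure stabilization).  On rectangular cells the bilinear
  mapping is affine and Q2 represents parabolas exactly, so plane-Poiseuille
  WSS is recovered to machine precision — the analytic anchor of the test
  suite.  Convection is stabilized with an advection-only streamline-upwind
  operator τ(u·∇φᵢ)(u·∇φⱼ), τ = [(2|u|/h)² + (4ν/h²)²]^{-1/2}; because it
  vanishes wherever u·∇u = 0, parallel-flow anchors are unperturbed.  The
  nonlinear strategy is: Stokes start → two relaxed Picard (Oseen) steps →
  the stabilization operator is frozen at that state (making it a fixed
  linear term of the discretization, so Newton's Jacobian is exact) →
  damped Newton, with pseudo-transient (SER) continuation as fallback.
  Convergence: normalized momentum and continuity residuals < 10⁻⁶.  All
  linear systems go through SuperLU; iteration order is fixed, so a given
  mesh + conditions reproduce bit-identical residual histories.
* **Boundary conditions.**  Dirichlet velocity at the inlet — either the
  fully developed parabola (default; lets short domains see developed flow
  at the first trench) or a uniform plug, in which case an entrance length
  ≥ 0.05·Re·H is required.  No-slip walls; natural ("do-nothing") outlet,
  which acts as a zero-gauge-pressure outflow.  The bulk-WSS condition is
  imposed through the Poiseuille relation U = τ_bulk·H/(6μ), never by
  iterating on the solved field.
* **WSS extraction.**  τ = μ |t·(∇u + ∇uᵀ)·n| at two Gauss points per
  wetted boundary edge, evaluated from the Q2 gradient of the wall-adjacent
  element; each sample carries its |dx| projection weight (exactly zero on
  vertical edges) and its arc-length weight.
* **Transport solver.**  Q1 Galerkin with conservative (divergence-form)
  advection plus an explicit outflow boundary term, and full-upwind
  isotropic balancing diffusion |u|h/2.  At the cell Péclet numbers of
  platelet transport (~10⁶) a monotone low-order scheme is the appropriate
  choice: the deposition contrast is a reaction-rate property, not a
  boundary-layer-resolved prediction.  θ-scheme stepping (implicit Euler
  default, Crank–Nicolson available), one LU factorization reused across
  steps.  Sub-percent negative undershoots that survive at sharp corners
  are clipped to zero each step; the clipped mass appears in the platelet
  budget, which otherwise closes to ~10⁻⁹ relative (inflow − outflow −
  Δbulk − deposited, with the inflow recovered from the unconstrained
  residual at the inlet nodes, so the identity is discrete-exact).

## Parameters and defaults

| Parameter | Default | Units | Why |
|---|---|---|---|
| μ, ρ | 3.5 cP, 1050 kg/m³ | — | whole blood, Newtonian approximation |
| clear height H | 0.508 mm | m | 0.02 in parallel-plate channel |
| viability band | 10–50 | dyn/cm² | physiological WSS retaining EC monolayers |
| bulk WSS | 600 | dyn/cm² | supraphysiological reference condition |
| trench count | 3 | — | the canonical simulated array |
| partitions (vertical fixture) | 100 µm | m | not printed anywhere; config-overridable |
| d (trapezoids) | 0 | m | partition tops are guaranteed above-band, so walls vanish |
| c_in | 3×10⁸ | PLT/ml | literature-typical platelet count |
| D_brownian | 1.58×10⁻¹³ | m²/s | platelet Brownian diffusivity |
| shear enhancement | 2.6×10⁻¹³·γ̇ | m²/s | Zydney–Colton-type augmentation |
| k(collagen), k(EC) | 10⁻⁶, 10⁻⁹ | m/s | 10³ reactivity contrast; literature-typical, not fitted |
| t_end | 3000 | s | the 50-minute deposition horizon |

The design space for optimization is h, w ∈ [0.01, 3] mm and α ∈ [2°, 88°].
The draft-angle interval keeps a numerical margin inside [0°, 90°]: α = 0
with d = 0 degenerates to a zero-thickness fin between merged trenches, and
tan α (hence the opening width) diverges at 90°.  The search is a
deterministic 3-level factorial scan followed by bounded Nelder–Mead
restarts from the best distinct scan points (an explicit initial simplex of
8% steps — the default simplex collapses at bound corners); every CFD
evaluation is cached by parameters, so the reported best f is reproduced
bit-exactly by re-evaluating the best design.

## Characteristic partition-top WSS

The WSS on a partition top is a plateau framed by two convex-corner
singularities where τ ~ r^{λ-1} (λ ≈ 0.54) diverges integrably.  The
length-weighted *mean* is therefore mesh-sensitive (it climbs ~20 points as
the corners are refined), while the length-weighted *median* tracks the
plateau and is stable across coarse/medium/fine meshes; the package reports
the median as the characteristic elevation (≈ +60% over bulk for the
700×400 µm vertical array), and keeps the mean available via
`WSSProfile.class_mean`.

## Study designs in tests and the acceptance run

* **Analytic anchors** run at fixed mean velocity (or reduced targets at
  the largest heights) because a 600 dyn/cm² target in a 2 mm channel
  implies Re > 2000, which the laminar guard refuses — the 6μU/h and
  τ ∝ 1/h_total checks are unaffected by the choice.
* **Optimization** runs at the `sweep` resolution with a 70-evaluation
  budget (40 in the test suite), each evaluation a full mesh→solve→f
  pipeline on a 3-trench domain; this keeps the whole search within a few
  minutes on one core while staying within a few percent of the
  coarse/medium-mesh objective values.
* **Width asymptote** is demonstrated at a 120 dyn/cm² bulk over a total
  height of 1.2 mm (trench 0.692 mm, 45° walls, one trench, widths
  1.5→12 mm).  At 600 dyn/cm² the total heights whose asymptotic floor WSS
  would fall inside the band (≈1.8–3.9 mm) imply separation bubbles far
  longer than any affordable width — the steady model is outside its
  comfort zone there — whereas at 120 dyn/cm² the flow reattaches within a
  few millimetres and f climbs toward its asymptote with shrinking
  increments.
* **Deposition contrast** compares collagen vs EC coatings of the trench
  interiors of the vertical array at t = 3000 s, 30–40 implicit steps.

## What the built-in scenarios do and do not show

The canned fixtures are idealized 2D periodic-like arrays under steady,
fully developed upstream flow.  Passing tests show that the numerical
pipeline reproduces analytic shear states exactly, the classic recirculating
cavity benchmark closely, discrete conservation identities to round-off, and
the qualitative sheltering physics (orders-of-magnitude floor throttling,
partition-top exposure, coating-controlled deposition contrast).  They do
not show anything about 3D end-wall effects, pulsatile flow, non-Newtonian
rheology at low shear inside trenches, EC biology (migration, mitosis, NO
secretion), or thrombus growth feeding back on the flow — all outside the
model.

## Known limitations

* At the supraphysiological reference condition the model ranks the 60°
  included-angle pilot trench above the 90° one and rates the reported
  large-trench optimum at f ≈ 0.40, while its own landscape peaks
  (f ≈ 0.63, refinement-stable) at micro-grooves at the lower size bound —
  a regime where a 10 µm groove cannot physically host 15–50 µm endothelial
  cells; the model scores geometry-conditioned shear only and knows no cell
  size.  Interpreting small-bound optima requires that biological caveat.
* Steady solutions over wide, deep openings (multi-millimetre separated
  shear layers) can fail to converge; such designs are reported as failed
  evaluations rather than extrapolated.
* The coverage objective of small trenches converges slowly under mesh
  refinement (the in-band strips on the sidewalls are sub-cell features at
  coarse resolutions); band-count quantities are reliable to a few percent
  at the default resolutions, not better.
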