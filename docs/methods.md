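# Methods

## Physical model and assumptions

The package models a polyelectrolyte hydrogel (the scaffold) immersed in a
NaCl solution bath between two ideal planar electrodes. Two mobile species,
Na⁺ and Cl⁻ (valences ±1), move by diffusion and electromigration; the gel
additionally carries bound anionic groups of magnitude c_f and valence z_f
= −1 that enter the charge density but do not move. The governing system is
the Poisson equation for the potential ψ, sourced by F(z₊c₊ + z₋c₋ +
z_f c_f)/(ε_r ε₀), coupled to a Nernst–Planck equation per species with the
mobility tied to the diffusivity by the Nernst–Einstein relation μ = D F /
(R T).

Deliberately excluded physics (out of the model's scope): convective flux
(the solvent is at rest), chemical reactions and electrode electrochemistry
(electrodes are ideal Dirichlet surfaces, representing a bath isolated from
electrolysis products), activity-coefficient gradients (ideal solution),
mechanical swelling/deformation coupling, and any cell-level response.

## Parameters

| Parameter | Symbol | Default | Units |
|---|---|---|---|
| Faraday constant | F | 9.6487×10⁴ | C mol⁻¹ |
| Gas constant | R | 8.3143 | J mol⁻¹ K⁻¹ |
| Temperature | T | 293 | K |
| Vacuum permittivity | ε₀ | 8.854×10⁻¹² | A s V⁻¹ m⁻¹ |
| Relative permittivity | ε_r | 100 | – |
| Ion diffusivity | D_k | 1.0×10⁻⁷ | m² s⁻¹ |
| Ion mobility | μ_k | derived: 3.9607×10⁻⁶ | m² s⁻¹ V⁻¹ |
| Fixed charge | c_f, z_f | 2.0, −1 | mol m⁻³, – |
| Bath concentration | c_sol | 1.0 | mol m⁻³ (= mM) |

These defaults define the validation scenario. Mobility may be stored
explicitly; a value inconsistent with Nernst–Einstein (beyond 10⁻⁴
relative) triggers a warning, not an error, since measured mobilities need
not satisfy the ideal relation. The relative permittivity of 100 is taken
as given by the parameter set; whether it is a physical estimate for the
hydrated medium or a regularization is not resolvable from the source
material, and the solver does not depend on the distinction. With these
values the Debye length at the bath concentration is √(ε_r ε₀ R T /
(2 F² c_sol)) ≈ 10.8 nm.

All user-facing units are SI; 1 mM ≡ 1 mol m⁻³ for concentrations, and the
configuration's `applied_mV` is the only non-SI convenience.

## Donnan oracle

At chemical equilibrium the gel concentrations follow from gel
electroneutrality (c₊ − c₋ + z_f c_f = 0 for z_f = −1) and the ideal Donnan
product c₊c₋ = c_sol². The implementation evaluates the larger root by the
non-cancelling branch of the quadratic formula and derives the smaller one
through the product, so the product law holds to machine precision even for
c_f ≫ c_sol. The Donnan potential is evaluated as Δφ(gel − bath) =
(R T / z_k F) ln(c_sol,k / c_gel,k) — the ratio direction that yields a
negative potential for an anionic gel — and is identical through either
species whenever the product law holds.

## Geometry and meshing

Domains are a 1D interval or a 2D rectangular bath with an embedded square
or circular gel, gel strictly interior, left/right exterior boundaries
tagged as electrodes and top/bottom as insulated. Meshes are conforming
(the gel–solution interface coincides with element facets) with a
refinement band of configurable half-width around each interface, built by
uniform-per-segment graded tensor grids (quads split into two triangles, or
four when mirror-symmetric meshing is requested).

The disc gel is produced by meshing a square gel of half-width equal to the
radius and morphing it with a square-to-disc blend map: the square contour
at inf-norm level m maps onto the circle of radius m inside the gel,
blending back to the identity at twice the radius. Interface vertices land
exactly on the circle, so the polygonal interface error shrinks with the
refined resolution (gel area within 1% of πr² at the default). Two
consequences are documented rather than hidden: generation element sizes
carry a 1.8× safety factor against the map's worst-case edge stretch, and
because a tensor grid cannot refine an annulus anisotropically, the fine
zone covers the full frame [center ± (r + band)] in both axes — wasteful
for thin bands but guarantees the resolution contract on the annulus.

The default geometry places a 5 mm gel at the center of a 15 mm bath with a
2 mm refinement band (the stimulation setting), and a `_scaled` variant
shrinks all lengths by 10⁴ (1.5 µm bath, 2 nm refined elements). Bulk
Donnan values are geometry-independent, which is what makes the scaled
variant quantitatively meaningful on one CPU; the full-scale fields would
require cluster-scale meshes (tens of millions of unknowns) to resolve
10 nm double layers and are therefore expressible but not desk-validated.

## Discretization and solvers

All three fields share one nodal Lagrange space — orders 1–3 on intervals,
1–2 on triangles, order 2 the default — stacked as (c₊, c₋, ψ), with Gauss
quadrature exact to degree 2·order. A row-sum lumped mass matrix is
available (`lumped_mass`) for transport tests and positivity-sensitive
runs; the consistent mass matrix is the default.

Steady problems drop the time term and solve the coupled nonlinear system
by monolithic Newton with an analytic Jacobian, Armijo-style backtracking
line search, and — if a cold start fails — continuation in the fixed
charge (ramping c_f in quarters, each stage warm-started). A Gummel-style
alternating fixed point was considered and not implemented: damped Newton
plus continuation converged in a handful of iterations on every scenario
tried, so the fallback would be dead code.

Transients use backward Euler with the full Newton solve per step. A step
fails if Newton does not converge or any nodal concentration drops below
−10⁻¹² c_ref (concentrations are never clipped, which would destroy
conservation); failed steps retry at half the step, and after five
consecutive successes the step doubles back toward the nominal Δt. The
default Δt of the scaled electrical preset (0.25 µs) covers the ~2.25×10⁻⁵ s
diffusion time of the scaled geometry in ~100 steps.

Nondimensionalization (default on) scales ψ by R T / F, concentrations by
the bath value, lengths by the bath extent and time by L²/D_ref; the
Poisson coupling becomes the inverse dimensionless squared Debye length
γ = F² c_sol L² / (ε_r ε₀ R T) (~10⁴ on the scaled geometry instead of
~10¹⁴ in SI). Newton tolerances (`newton_abs_tol`, default 10⁻¹⁰ RMS)
apply to the residual in these scaled variables. Sparse linear systems are
solved by SuperLU through scipy.

Boundary conditions: Dirichlet rows are replaced in residual and Jacobian.
When a scenario has no potential Dirichlet datum anywhere (an all-insulated
box), the Poisson block is pure-Neumann and singular; one potential dof is
pinned to 0 V. Such a closed box must also be globally electroneutral —
otherwise Gauss's law is incompatible with zero-flux walls and the
discrete system is inconsistent; the conservation tests construct their
initial states accordingly.

## Stimulation protocols

*Chemical*: both electrodes at 0 V, concentrations pinned to bath values,
uniform initial state. *Electrical*: the anode at the applied voltage
(default 50 mV, anode side configurable), cathode at 0 V, concentrations
pinned at bath values on both electrodes (a well-stirred bath), initial
state the chemical-equilibrium solution. Two conventions here are genuine
choices, since only the total applied potential and the bath molarity are
fixed by the scenario: the split of the applied voltage across the two
electrodes (all on the anode, cathode grounded) and the Dirichlet (rather
than no-flux) treatment of electrode-side concentrations. Both are
configurable; the qualitative cathode/anode asymmetry does not depend on
them.

## Steady-state detection

A transient is steady from the earliest time after which the relative rate
max over fields of ‖Δf‖∞ / ‖f‖∞ / Δt stays below tolerance. The default
tolerance, 10⁻⁸ s⁻¹, suits full-scale runs whose transients span hundreds
of seconds. Rates scale inversely with the diffusion time, so the scaled
presets carry their own tolerance (10 s⁻¹ ≈ relative change 2.5×10⁻⁶ per
step); a single absolute default cannot serve both geometries. Because the
threshold is expressed per unit physical time, the detected steady time is
stable under time-step halving, which the tests assert.

## What the scaled scenarios do and do not show

The desk-scale suite validates: exact Donnan recovery in the bulk (≤0.5%,
observed ~10⁻⁸ relative), bulk electroneutrality away from the interfaces,
mirror symmetry and polarity-swap mirroring, exact discrete conservation
under no-flux boundaries, nodal agreement with an independent dense
brute-force PNP assembly, first-order backward-Euler convergence and
order-(p+1) spatial convergence on manufactured solutions, and the
qualitative electrical-stimulation result — ion enrichment at the
cathode-side interface, depletion at the anode side, both gel ions higher
on the cathode side. It does not reproduce full-scale interface profiles
or the ~800 s full-scale settling time: interior double layers at 15 mm /
10 nm scale separation are beyond a single-CPU mesh, and the steady time
depends on the (unstated) tolerance behind any such figure.

## Numerical edge cases

- Degenerate inputs are rejected with named errors: non-positive
  diffusivities, zero valences, charged baths, gels touching the bath
  boundary, meshes with missing tags, non-positive time steps.
- Line-profile extraction interpolates with the element basis and refuses
  points outside the domain (no extrapolation).
- The electroneutrality metric assigns interface nodes to the closed gel
  region (they carry the fixed-charge contribution); its bulk variant masks
  nodes within 5 Debye lengths of the interface by default.
- Exports are byte-deterministic: full-precision `repr` floats, no
  timestamps.

## Known limitations

1D/2D only; triangles up to order 2; no adaptive (error-driven) refinement;
no electrode kinetics, AC stimulation, convection, reactions, or
mechanical coupling; the monovalent binary electrolyte is assumed by the
Donnan oracle and the bundled scenarios (the PDE core itself only assumes
two species).
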