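# gelpnp

Finite-element simulation of coupled electro-diffusive ion transport
(Poisson–Nernst–Planck) in a fixed-charge polyelectrolyte hydrogel immersed
in a NaCl bath — the setting of electrically stimulated hydrogel scaffolds
for cartilage–tissue engineering. The package is aimed at modellers who want
to predict how ion concentrations and the electric potential distribute in
and around a scaffold under chemical (Donnan) equilibration or
constant-voltage electrical stimulation, without a commercial FE stack.

## Model

Two mobile monovalent species c± and the potential ψ are coupled through

- Poisson's equation sourced by the net ionic charge, including the bound
  anionic groups of the gel network (concentration c_f, valence z_f,
  supported only on the gel region):

  ∇²ψ + (F / ε_r ε₀) (z₊c₊ + z₋c₋ + z_f c_f) = 0

- the Nernst–Planck equations with diffusive and electromigrative flux
  (convection and reactions absent, activity coefficients uniform):

  ∂c_k/∂t = ∇·(D_k ∇c_k + z_k μ_k c_k ∇ψ),  μ_k = D_k F / (R T)

Both are discretized with nodal Lagrange elements (order 2 by default) on a
conforming bath+gel mesh with local refinement bands around the gel–solution
interface, where the electric double layers (Debye length ≈ 10 nm at 1 mM,
ε_r = 100) live. Steady states are solved by damped monolithic Newton with
an analytic Jacobian; transients use backward Euler with adaptive step
halving. Internally the system is nondimensionalized (ψ in thermal-voltage
units R·T/F, concentrations relative to the bath, lengths relative to the
bath extent), which tames the F/ε_rε₀ ≈ 10¹⁴ coupling.

The analytic validation oracle is the ideal Donnan equilibrium: gel
electroneutrality plus the product law c₊c₋ = c_sol² give closed-form gel
concentrations, and

  Δφ = (R T / z_k F) · ln(c_sol,k / c_gel,k)

gives the potential jump across the interface (negative for an anionic gel).

## Worked example

The closed-form Donnan equilibrium for a gel with 2 mol/m³ fixed anionic
charge in a 1 mM (= 1 mol/m³) NaCl bath at 293 K:

```sh
$ gelpnp donnan --fixed-charge 2 --bath 1
{
  "donnan_potential_mV": -22.252793572865563,
  "gel_anion_mM": 0.4142135623730951,
  "gel_cation_mM": 2.414213562373095
}
```

The counter-ion (Na⁺) is enriched in the gel to 2.414 mM, the co-ion (Cl⁻)
expelled to 0.414 mM, and the gel floats −22.25 mV below the bath.

The same numbers emerge from the full PDE solve of the chemical-stimulation
scenario on the bundled desk-scale preset (a 1.5 µm 1D bath–gel–bath
geometry whose 2 nm refined elements resolve the double layers; bulk Donnan
values are geometry-independent, so shrinking the domain does not change
them):

```sh
$ gelpnp run --preset paper_table1_chemical_scaled --out results/
{
  ...
  "gel_center": {
    "Cl-": 0.4142135712712521,
    "Na+": 2.4142135712679473,
    "potential": -0.022252784920785095
  },
  "potential_jump_V": -0.022252784919892705,
  ...
}
```

The gel-center concentrations and potential jump agree with the closed form
to nine significant figures. `gelpnp run --preset
paper_table1_electrical_scaled` continues from this equilibrium with 50 mV
applied and reports the steady-state time and the cathode/anode asymmetry;
`gelpnp mesh` writes any configured mesh as Gmsh MSH with region and
boundary tags, and `gelpnp postprocess` extracts line profiles (CSV) and
VTK fields from saved checkpoints.

Full-scale presets (`paper_table1_chemical`, `paper_table1_electrical`,
15 mm bath) are included for completeness; resolving 10 nm double layers on
that geometry requires cluster-scale meshes, so their summaries are not
quantitative on desk hardware.

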