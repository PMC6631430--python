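# Methods

## Flow model

The package models steady electro-osmotic flow (EOF) through a slit of
width `w = 20 nm` whose walls carry surface charge `σ_s` and a grafted
polymer coating. The flow is one-dimensional: all fields depend only on
the slit coordinate `z` (origin at the center of the innermost
bottom-wall atom layer). The velocity obeys the Navier-Stokes-Brinkman
(NSB) balance of viscous stress, distributed coating drag, and electric
body force,

    d/dz[μ(z) u'] − 6π μ(z) n(z) a_bead K(φ(z)) u + ρ_e(z) E_ext = 0,

solved as a linear two-point boundary-value problem on the half slit
`[0, w/2]` with `u = 0` at the hydrodynamic wall plane and `u' = 0` at
mid-slit; the full profile is the mirror image. The drag term treats
each bead as a Stokes sphere of effective radius `a_bead`; `K(φ)`
corrects for hydrodynamic correlations among neighbouring spheres at
volume fraction `φ`.

Assumptions: Stokes (inertialess) flow; electrostatics decoupled from
hydrodynamics (the ion profiles are *inputs*, not solved
self-consistently with the flow); a position-independent `a_bead`;
viscosity given by the dilute Einstein law `μ = μ0(1 + 2.5 φ)`.

The driving term is implemented with signed valences,
`ρ_e = F Σ_i z_i c_i`, since an unsigned sum would let a neutral
electrolyte drive flow. The hindrance function defaults to the
Kim-Russel rational fit for the drag on random fixed arrays of spheres
(`K(0) = 1`, increasing up to random close packing `φ = 0.64`); a
`"unity"` model recovers the plain dilute swarm drag. Because the exact
hindrance expression behind the original analysis is not specified in
the text available to us, the function is pluggable; at the volume
fractions of these coatings (`φ ≲ 0.1`) the choice shifts mid-slit
velocities by only a few percent and does not affect noiseless fit
round trips (the same `K` appears in the forward and inverse model).

## Numerics

Conservative-flux second-order finite differences on a uniform grid:
face fluxes use harmonic-mean viscosities, so viscosity jumps aligned
with cell faces are captured without loss of order; the mid-slit Neumann
condition uses a reflected ghost node. The resulting tridiagonal system
is solved directly (`scipy.linalg.solve_banded`). Against an independent
closed-form piecewise-constant-coefficient solution, the solver is
accurate to better than 1e-4 relative (max norm) at ~4000 grid points
and converges at second order. Default grid: 2001 nodes over the full
slit (the midpoint must be a node, hence odd counts).

Radius inference minimizes the root-mean-square velocity mismatch over
`a_bead ∈ [0, a0]` by bounded Brent search (`xatol = 1e-7 nm`); the
residual is also evaluated at both bounds, and a boundary optimum is
flagged (monotone residual = no interior minimum). An optional mask can
exclude a near-wall strip from the metric where solvent layering
artifacts would live in real data; it is off by default. Orientation
averages of tabulated Stokes radii integrate the piecewise-linear
interpolant of the table on a dense sub-grid (2e4 points), under either
the hemisphere measure `sin θ dθ` (default — consistent with the
measured isotropy of near-bead orientations) or uniform-in-θ.

## Units

Inputs follow molecular-simulation conventions: lengths in nm,
concentrations in mol/L, fields in V/nm, viscosity in Pa·s, drag forces
in kJ/(mol·nm) (converted per molecule via Avogadro's number).
Velocities are reported in m/s. Defaults: `μ0 = 0.85e-3 Pa·s`
(bulk-water-like), `a0 = 0.156 nm`, `E_ext = 1.6e-2 V/nm`,
`σ_s = 3.28e-2 C/m²`, ionic strength `3.4e-2 mol/L`, `T = 300 K`,
`ε_s = 78`. All are configurable.

## Synthetic data generator

The generator stands in for molecular-simulation outputs and defines the
conditions under which the package is exercised.

**Coatings.** Chains with `3N + 2` free beads (united-atom counting:
three backbone beads per monomer plus two terminal beads; the two anchor
beads are not free) are grown as freely-rotating walks: bond length
`b = 0.15 nm`, fixed tetrahedral bond angle, uniform dihedral, grafted
on a square lattice (`a = 2.5 nm`) on both walls. A hard core of one
bead diameter `2 a0` applies between chains, against the walls, and
within a chain for beads at least four bonds apart — closer pairs
*cannot* avoid overlap, because the bond length is smaller than the bead
diameter (overlapping united atoms are a deliberate feature of the bead
model). Growth is by per-bead rejection with whole-chain restarts; an
overcrowded specification fails loudly, naming the chain. The generated
coatings reproduce the structural signatures that matter here: a
delta-like first RDF peak at `b`, a second peak at the bond-angle
distance `2b sin(54.75°) ≈ 0.245 nm`, and bead counts conserved exactly.
They do not reproduce force-field-specific dihedral statistics or
solvent-induced structure — conclusions about those do not transfer from
passing tests.

**Double layers.** Analytic Gouy-Chapman profiles for a 1:1 electrolyte:
surface potential from the Grahame equation, single-wall potential
superposed from both walls (exact in the thin-double-layer regime
`λ_D ≈ 1.65 nm ≪ w`), ion concentrations by Boltzmann weighting. The
profiles satisfy electroneutrality against the wall charge to <0.5%.
Real (simulation-derived) ion profiles can be substituted anywhere — the
solver only sees tabulated `c_i(z)`. The stated ionic strength of the
reference experiments is ambiguous in the source material (3.4e-2 vs
0.56 mol/L); the default is 3.4e-2 mol/L, exposed in `ElectrolyteSpec`.
Likewise the grafting density 0.164 nm⁻² and the lattice constant
2.5 nm (→ 0.16 nm⁻²) are mutually inconsistent; the lattice constant
wins. The physical bead radius is quoted inconsistently as 0.156 and
0.153 nm in the source figures; 0.156 nm is the default.

**Scenarios.** A `SyntheticScenario` assembles density (parametric
parabolic brush by default, Gaussian mushroom or an explicit coating as
alternatives), double layer, and applied field, forward-solves with a
planted `a_bead`, and optionally adds i.i.d. Gaussian velocity noise
under a seed (zero noise returns the solver output bit-identically). The
parametric layer height defaults to `a (N/14)^0.65` — a gyration-like
growth law anchored so the layer extent equals the grafting separation
at the brush/mushroom crossover `N = 14`; the areal bead density is
fixed by the lattice (one chain of `3N+2` beads per cell per wall).

**Free chains.** The pivot algorithm on the simple cubic lattice samples
self-avoiding walks (random non-identity octahedral symmetry applied
beyond a random vertex; O(1) hash-set collision checks). Defaults:
equilibration `max(500, 5N)` attempted moves from a straight rod, one
sample per 8 attempts — enough that the gyration radius decorrelates.
With excluded volume off, ideal walks are drawn directly. At
`N = 50–400` the fitted effective exponent is 0.59–0.60, consistent with
the Flory value 0.587 plus finite-chain corrections.

## Structure statistics

The RDF is deliberately *non-normalized* (counts per reference bead per
spherical-shell volume, not divided by a bulk density) because the bead
density in a grafted coating is strongly inhomogeneous; a raw-counts
variant is selectable. Minimum-image convention applies in x,y only
(walls bound z). Near and far beads are split at `r0 = 0.3 nm`, inside
which the structure is intra-chain and independent of `N`.

A far bead is *exposed* to a reference bead when no third bead lies
within the occlusion diameter `d_occ = 2 a0` of the open segment joining
them, with its perpendicular projection strictly inside the segment
(endpoints never occlude). `n_far(r)` is the mean number of exposed
partners per reference bead *per unit separation* (nm⁻¹), measured for
reference beads in a slab (default `z = 1 nm ± 0.15 nm`), so that
`∫ n_far dr` is a count and the shielding average is dimensionless.

Orientation distributions project neighbour displacements at a given
shell radius into the (x,z) or (x,y) plane (slab tolerance `0.5 a0`
around the plane) and histogram the angle to the flow direction,
normalized by the bin mean.

Gyration radii are RMS distances to the chain centroid; the scaling
exponent `γ` comes from a least-squares line through
`log R_g` vs `log N` (exact to 1e-10 on noiseless power laws). Chains
classify as mushroom (`R_g < a`), brush (`R_g > a`) or crossover.

## Shielding model

The additive average
`a_bead(N) = a_near − ∫∫ [a_near − a(r,θ)] P_far(r,θ;N) dr dθ` uses
trapezoidal quadrature on the kernel grid, with
`P_far = ½ n_far(r) sin θ` on `θ ∈ [0°, 90°]` exactly as defined in the
model (note its θ-integral is `n_far/2`, not `n_far`; the normalization
is kept as printed rather than "fixed"). The kernel — the Stokes radius
of a bead flanked by one far-bead pair at `(r, θ)` — is supplied as a
CSV table in real use; tests and examples use a parametric family
`a(r,θ) = a_near[1 − A e^{−(r−r0)/λ} g(θ)]` with `g` decreasing to
`g(90°)`, which reproduces the qualitative saturation of the measured
kernel. The default `a_near = 0.18 a0` is the near-bead (bonded
neighbour) shielding value. Results are clamped at zero with a warning
when the far-bead mass is large enough to break the additivity
assumption (total weight > 1 also warns); quadrature error is < 1e-4
relative under grid doubling on smooth kernels. The shielding radius
`r_s(θ)` is the smallest grid distance beyond which the kernel stays
within a tolerance (default 5%) of `a_near`.

## Design choices that were genuinely open

- **Occlusion rule.** "No other bead between them, within a bead
  diameter" is read as a perpendicular point-to-segment test with
  interior projection; the threshold is a parameter.
- **Orientation-average measure.** The hemisphere measure `sin θ dθ` is
  the default (uniform on the sphere, matching the observed isotropy);
  uniform-in-θ is selectable and reported alongside in diagnostics.
- **No-slip plane.** At `z = 0` by default, with a configurable offset,
  since the hydrodynamic wall position is not part of the model
  specification.
- **K(φ) placement.** The drag enhancement multiplies the Stokes term
  (hindered-settling convention); the dilute limit is unaffected.

## Problem sizes

Default study sizes: 2001-node grids; 50-chain coatings for RDF
statistics; SAW ensembles of 2000 samples at N ∈ {50, 100, 200, 400};
20 replicates for noisy-fit round trips. These were chosen so every
statistic has comfortable margins over its sampling noise while the full
analysis remains a desk-scale computation.

## Known limitations

- No molecular dynamics: drag-force tables and shielding kernels are
  *inputs*; the package never computes them from trajectories.
- The 1D NSB model has no coupled electrostatics, no time dependence,
  and no lateral structure; `a_bead` is a single global parameter.
- Additive far-bead shielding ignores collective effects and partially
  exposed beads; it is a qualitative model of the N-dependence, not a
  replacement for the profile-matching fit.
- The coating generator emulates geometry and counting statistics, not
  force-field thermodynamics; brush heights of the parametric profiles
  follow a fixed growth law rather than a self-consistent theory.
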