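# Methods

## Model

pbsakit computes end-state binding free energies under the
single-trajectory protocol (STP). All three species — complex, receptor,
ligand — share the coordinates of the complex trajectory, so every
intramolecular contribution (bonds, angles, torsions, intra-group
non-bonded) is identical in the bound and unbound states and cancels
exactly in the binding difference. What remains, per snapshot, is

    ΔH(i)  = ΔE_elec(i) + ΔE_vdW(i) + ΔΔG_polar(i) + ΔΔG_non-polar(i)
    ΔG     = ⟨ΔH⟩ + (−TΔS)

The method inherits the usual end-state assumptions: implicit solvent
replaces explicit water, conformational response to unbinding is
neglected (STP), and the entropy term is estimated from energy
fluctuations rather than from normal modes.

### Vacuum molecular mechanics

Electrostatics and Lennard-Jones energies are full double sums over
receptor × ligand pairs with **no distance cutoff** — end-state systems
are desk-scale, and a cutoff would break the translation/rotation
invariance the tests assert to 1e-8 kcal/mol. For salty media an
optional Debye–Hückel damping multiplies each Coulomb pair by
exp(−r_ij/λ_D), with

    λ_D = sqrt(ε₀ ε_r k_B T / Σᵢ nᵢ e² zᵢ²)

summed over all mobile ion species (nᵢ = number density from the molar
concentration). For 0.15 mol/L 1:1 salt at 298.15 K this gives
7.85–7.93 Å depending on ε_r (78.4–80); the package default is ε_r = 80.
Screening applies only to the inter-group Coulomb term, not to LJ or to
the PB solve (which carries its own ionic term). The unscreened Coulomb
sum uses ε_in = 1 (vacuum); when screening is on, ε_in comes from the
screening parameters, since the damped formula is written with ε_in
inside.

LJ cross terms default to geometric-mean combination on C6 and C12;
Lorentz–Berthelot is available. The sidecar may carry σ/ε instead, which
convert as C6 = 4εσ⁶, C12 = 4εσ¹².

Per-atom decomposition assigns half of each pair energy to each partner;
this is symmetric, conserves totals by construction, and is the
convention residue decomposition inherits.

### Polar solvation: finite-difference linear PB

The linearized Poisson–Boltzmann equation

    ∇·ε(r)∇φ(r) − κ̄²(r) φ(r) = −4π ρ_f(r)

is discretized on a uniform 7-point grid. Linearization (sinh φ ≈ φ) is
appropriate at the low ionic strengths (≈0.15 mol/L) these calculations
target. Numerical choices:

- **Units.** Charges in e, lengths in Å, φ in Gaussian-style units where
  an isolated charge obeys φ = q/(εr); energies convert with
  k_coul = 332.0637 kcal·mol⁻¹·Å·e⁻².
- **Dielectric.** Solute interior = union of atom spheres at `pb_radius`
  (van der Waals surface, not a molecular surface — a deliberate
  simplification; it is deterministic and adequate for the validation
  battery, but differs from solvent-excluded-surface codes). Edge
  dielectrics use *fractional harmonic averaging*: the signed distance
  to the solute surface is interpolated along each edge and the inside
  fraction f weights 1/ε = f/ε_in + (1−f)/ε_out — the 1-D exact result
  for an interface crossing the edge. This makes the Born-ion energy
  converge smoothly and monotonically with spacing (−2.1%, −1.0%,
  −0.4% at 0.8, 0.6, 0.4 Å), where naive node labelling oscillates with
  grid registration.
- **Ions.** κ̄² = ε_solvent/λ_D² beyond a Stern layer (atom radius +
  2.0 Å ion probe), zero inside.
- **Charges.** Trilinear spreading to the 8 surrounding nodes; the grid
  total equals the molecular charge to 1e-9 e. Potentials are read back
  at atom centres with the matching trilinear interpolation.
- **Boundary.** Dirichlet faces from a sum of per-atom screened
  monopoles q_i exp(−r/λ_D)/(ε r) (the standard "multiple Debye–Hückel"
  condition). A single lumped monopole and a grounded boundary are
  selectable, but the per-atom sum is the default because it is the only
  variant whose boundary error cancels consistently between the complex
  (often net-neutral) and the charged sub-systems on a shared grid; with
  the lumped monopole a separated ion pair shows ~20 kcal/mol of
  spurious ΔΔG_polar, with the per-atom sum the same system reproduces
  the analytic 332(1/ε_s − 1/ε_in)q₁q₂/r limit to <1%.
- **Solve.** Jacobi-preconditioned conjugate gradient on the symmetric
  positive-definite operator, relative residual ≤ 1e-6 (default),
  deterministic for fixed inputs.
- **Reaction-field subtraction.** G_polar = ½Σq_i[φ_solv − φ_ref](r_i),
  with φ_ref solved on the *identical* grid with homogeneous ε_in and no
  salt. This removes the spacing-dependent grid self-energy exactly: a
  charge with ε_solvent = ε_in yields exactly zero at any spacing.
- **Same-grid discipline.** ΔΔG_polar differences complex, receptor and
  ligand solves on one grid geometry (the complex bounding box plus a
  10 Å margin by default) so discretization artifacts cancel.

Defaults: spacing 0.5 Å, margin 10 Å, ε_in = 2, ε_solvent = 80, no salt.
These are field-standard continuum-electrostatics values; all are
configurable. Exact numerical parity with external PB codes is not
claimed (different surface definitions and charge anti-aliasing).

### Non-polar solvation: Shrake–Rupley SASA

Per-atom accessible areas use a golden-spiral (Fibonacci-lattice) point
set — deterministic, no RNG, hence bit-reproducible — with
neighbour-sphere occlusion; an isolated atom is exact at any point
count. Because the point set is fixed in the world frame, mirror-image
configurations agree only to the sampling resolution (≲1% at the default
960 points) and whole-system rotations to <0.2%, both asserted in tests.
The linear model G = γA + b uses γ = 0.00542 kcal·mol⁻¹·Å⁻²,
b = 0.92 kcal·mol⁻¹ (the widely used MM-PBSA SASA parameterization).
The offset b is applied once per molecular species, so the binding
difference is γΔA − b; a `cancel` mode drops the offset from the
difference for users who prefer the surface-only convention.

### Interaction entropy

−TΔS = k_B T ln⟨exp(ΔE_MM(i)/k_B T)⟩ over the *inter-group* interaction
energy series E_MM(i) = ΔE_elec(i) + ΔE_vdW(i) — under STP the
intramolecular terms carry no fluctuation information about binding, so
the inter-group series is the natural argument. The exponential average
is evaluated with log-sum-exp, so arbitrarily large fluctuations do not
overflow. The estimator is non-negative (Jensen) and invariant under
shifting the series; both are property-tested. Tiny negative values from
floating-point cancellation on constant series are clipped to zero.
A caveat inherited from the estimator itself: for wide energy
distributions (fluctuation SD ≳ k_BT) the exponential average converges
slowly in the number of frames and the estimate is a lower bound in
practice.

### Statistics

ΔG_expr = RT ln K_i converts inhibition constants (mol/L) to free
energies. Correlations follow the printed textbook forms: Pearson from
centred products, Spearman as 1 − 6Σd²/(n(n²−1)) on average ranks, and
Kendall tau-a = 2(n_c − n_d)/(n(n−1)) with no tie correction; on
tie-free data all three match scipy.stats to 1e-10 (asserted).

### Alanine scanning

A receptor residue is truncated to alanine by deleting side-chain atoms
beyond Cβ. Retained atoms (backbone, Cβ, its hydrogens) keep their
coordinates bit-exactly — no geometry is rebuilt — and their charges are
reset from a bundled alanine template (Amber-style, net neutral) so the
truncated residue is chemically sensible. GLY (no Cβ), PRO (backbone
ring) and ALA itself are rejected; Cβ sites left with fewer than three
hydrogens (united-atom inputs) are kept as-is with a log note. The
wild-type energies are computed once and shared across all mutants;
failure of one residue does not abort a scan. How the original program
family recharges truncated residues is generally not published; the
template approach is this package's own, documented choice, and users
comparing absolute ΔΔG values across tools should expect differences.

## Synthetic data

The toy generator places non-overlapping atoms (rejection sampling,
min. separation 2.5 Å) with charges in ±0.5 e, σ in 2.5–3.5 Å, ε in
0.05–0.2 kcal/mol and PB radii in 1.2–2.0 Å — typical magnitudes for
organic/protein heavy atoms — and emits a short trajectory by adding
0.15 Å Gaussian jitter per frame. It emulates the *shape* of real
inputs (multi-frame coordinates plus per-atom parameters, an interacting
interface, frame-to-frame fluctuation) but not their physics: no bonded
structure, no equilibrated ensemble, no water-mediated correlations.
Passing tests therefore demonstrate correctness of the energy machinery
and its conservation/limit properties, not predictive accuracy on real
protein–ligand systems, which depends on force field, sampling and PB
parameterization quality. Canonical analytic fixtures (`born_ion`,
`two_ion_dimer`, `lj_dimer`, `homo_dimer`) pin the solvers to closed
forms.

Test and demonstration runs use deliberately small problem sizes —
~10-atom systems, 3-frame trajectories, 0.6–0.9 Å PB grids with 6–8 Å
margins, 120–480 SASA points — chosen so the whole validation battery
executes in minutes on one core while every oracle tolerance is still
met; the Born-ion acceptance check runs at the production default
resolution (0.4 Å).

## Degenerate inputs and tie-breaks

Coincident inter-group atoms raise a singularity error naming the pair;
zero ionic strength yields an infinite Debye length (screening factor
1); a zero-charge PB problem returns φ ≡ 0 without solving; empty frame
series, single-frame entropy requests and zero-variance correlation
inputs raise typed errors rather than returning NaN. Solvent residues
(SOL/WAT/NA/CL...) found in the sidecar are dropped with a warning, and
atom ids are renumbered contiguously (original ids retained) whenever
atoms are removed.

## Known limitations

- van der Waals surface instead of a molecular (solvent-excluded)
  surface in the PB dielectric; expect small systematic differences from
  SES-based codes.
- Linear PBE only; very high ionic strengths or highly charged surfaces
  would need the nonlinear equation.
- No periodic-boundary repair: the trajectory reader only warns when an
  intra-solute span exceeds half the box.
- Single-trajectory protocol only; systems with large binding-induced
  conformational change need a multi-trajectory treatment this package
  does not provide.
- Interaction entropy is the only entropy estimator; no normal-mode or
  quasi-harmonic option.
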