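# Methods

This note records the models implemented in wetbind, the numerical choices
behind them, and what the synthetic test systems do and do not establish
about real data.  Units throughout: Å, kcal/mol, elementary charge, amu,
ps, K.

## Molecular-mechanics terms

Nonbonded energies are exact pair sums over finite snapshots — no cutoff,
no Ewald.  Electrostatics use Coulomb's law with k_e = 332.0637
kcal·Å/(mol·e²); Lennard-Jones terms use the Rmin/ε convention with
Rmin_ij = Rmin_half_i + Rmin_half_j and ε_ij = √(ε_i ε_j).  Two per-atom
charge sets coexist: the MM set feeds these terms, a separate PARSE-style
set feeds the continuum-electrostatics stage.

Solute–solute interaction terms default to a uniform dielectric of 2.0
(screening of the protein interior in post-hoc snapshot energies);
explicit-solvent water energies use 1.0.  Ligand internal energies comprise
electrostatic, van der Waals and proper-torsion contributions only — bond,
angle and improper terms are excluded by design, since the deformation
penalty is defined as the bound/unbound difference of exactly these three
channels and bonds to hydrogen are constrained in the simulations this
analysis targets.  Nonbonded exclusions are derived from the bond list
(1-2 and 1-3 excluded); the 1-4 scaling factor is a configuration
parameter defaulting to 1.0 (full strength), since no single convention is
universal across force fields.

The deformation penalty differences only the *ligand's* internal energy.
The receptor's internal energy is never differenced: it is the small
difference of two very large numbers and would dominate the error budget.

## Poisson–Boltzmann desolvation

The linearized PB equation is discretized on a cubic lattice with face-
centred dielectrics and solved by red-black successive over-relaxation
(ω = 1.9, relative residual tolerance 1e-6).  The dielectric boundary is
the solvent-excluded surface built on a 2× refined lattice by
morphological closing: probe-accessible lattice points are those at least
1.4 Å outside every atom, the solvent region is everything within the
probe radius of an accessible point (computed with a Euclidean distance
transform), and the interior is the complement unioned with the van der
Waals volume.  Face dielectrics combine the two half-edges in series
(harmonic weights 1:2:1 over the endpoint and midpoint samples), which is
what makes the Born-ion test converge at the percent level.  Ions are
excluded from the solute interior and from a 2.0 Å Stern shell; κ² is
computed for a 1:1 salt at 300 K.

Focusing: by default three same-dimension grids with geometrically
decreasing spacing, the coarsest spanning the solute plus a 20 Å margin
with Debye–Hückel analytic Dirichlet boundaries, each finer level taking
its boundary by trilinear interpolation from the previous solution.  The
default lattice dimension is 129; the test suite uses 33–65-point grids,
which the Born benchmark shows are already accurate at sub-percent level
when the finest spacing is ≲0.3 Å.

Solvation energies are reaction-field differences: a matched solve with
homogeneous ε_in and zero salt on the identical finest grid is subtracted,
cancelling the grid self-energy.  Consequences worth knowing: (i) the
energy of a multi-solute system contains the screened cross-interaction
k_e q_i q_j (1/ε_out − 1/ε_in)/r between separated charge groups — the
two-ion additivity test accounts for it explicitly; (ii) the discretization
error oscillates slightly with how the dielectric boundary straddles grid
faces, so convergence-with-refinement is asserted at fixed spacings
(0.6/0.45/0.3 Å) rather than as a smooth rate.

ΔG_PB differences three solves (complex, receptor, ligand) on identical
grid geometry per frame, taken from the complex's focusing ladder, so
lattice noise largely cancels.  Per-residue PB contributions keep the
receptor intact and delete every other ligand atom; the per-residue sum is
*not* constrained to match the whole-ligand value, because deleting atoms
changes the dielectric boundary.

The SASA term uses a Shrake–Rupley implementation with a deterministic
golden-spiral quadrature (960 points by default, ≤0.5 % error on a lone
sphere) and the linear model 0.00542·ΔSASA + 0.92; per-residue mode drops
the constant.

## Quasiharmonic conformational entropy

Frames are superposed onto the iteratively refined average structure by a
mass-weighted Kabsch fit, projecting out translation and rotation.  The
mass-weighted covariance of the residual fluctuations is diagonalized;
each eigenvalue λ maps to ω = √(k_B T/λ), the six smallest-eigenvalue
modes are discarded *by rank* (deterministic, no threshold), and the
quantum harmonic-oscillator entropy is summed at 298 K.  Extra near-zero
modes beyond the expected six trigger a rank-deficiency warning.  With a
known generating covariance confined to the internal subspace, recovered
frequencies match the closed form within 5 % at 10⁴ frames; a rigid-body
trajectory yields exactly zero entropy after projection.

## Hydration sites

Clustering is greedy density clustering of water-oxygen samples pooled
over frames: repeatedly take the sample with the most neighbours within
the site radius (1.0 Å) as a center, delete everything within the
exclusion radius (2.4 Å), stop when the best remaining count falls below
min_occupancy × n_frames (0.25).  Ties break on the lexicographically
smallest coordinate, making the result invariant to frame order.  The
radii are WaterMap-style conventions and are exposed in the call
signature.

Occupancy counts frames with ≥1 water oxygen in the site (nearest taken if
several), keeping it in [0, 1].  Site enthalpy is the mean nonbonded
energy of the occupying water with the entire rest of the system (not
halved), minus the bulk reference.  Site entropies are first-order IFST
estimates at 300 K, reported as −TΔS so that ordering is a positive,
unfavourable number:

* translational: −k_B⟨ln(ρ_site/ρ_bulk)⟩ with ρ_site estimated by the
  Kozachenko–Leonenko k-nearest-neighbour estimator (k = 1 by default;
  unbiased at the sample counts available, where histograms are not);
  ρ_bulk defaults to 0.0334 Å⁻³.
* orientational: the same estimator on the rotation manifold with the
  geodesic (rotation-angle) metric; the measure of a geodesic ball of
  radius r under normalized Haar measure is (r − sin r)/π, scaled by the
  molecular symmetry number (2 for water, i.e. H-relabelling).  Coincident
  samples saturate the estimator at a finite cap with a warning.

dG = dH + (−TΔS) holds exactly by construction, as do the
occupancy-weighted values (occupancy × raw).  Apo-vs-bound comparison:
an apo site matched to a bound site within 1.5 Å is *stabilized*
(ΔΔX = bound − apo, weighted); an unmatched apo site with a ligand heavy
atom within 2.0 Å is *displaced* — its water returns to bulk, so binding
gains −(apo excess); anything else is unchanged.  No occupancy-entropy
cross term is included (first-order expansion only).

The fixed-point probe analysis (1.4 Å sphere, placed directly or at a
distance along an atom-pair vector resolved per frame) reports occupancy
and mean enthalpy versus bulk with a 20-block standard error.

## The bulk-water reference and the Monte Carlo sampler

The bulk reference is the mean environment energy of a water molecule in
neat water.  It is produced by a Metropolis Monte Carlo sampler of rigid
3-site waters with TIP3P parameters in a periodic cubic box: the
observable is configurational, so MC sampling is an exact substitute for
molecular dynamics here, and the periodic box avoids the surface
trimming a droplet simulation requires.  Moves are single-molecule random
translations (±0.15 Å per axis) and rotations (±0.25 rad about a random
axis through the oxygen); pair energies use a molecule-based (O–O)
minimum-image cutoff of 8.5 Å with no long-range correction.  Snapshots
are separated by at least N accepted moves (N = number of waters);
equilibration defaults to 500 attempted sweeps from a simple-cubic start.
Acceptance rates are logged and recorded in the trajectory provenance.

Measurement and sampling conventions differ deliberately: the sampler
truncates at 8.5 Å for speed, while the environment-energy measurement
sums all minimum-image pairs.  At the default conditions (216 waters,
0.997 g/cm³, 300 K, 200 snapshots, ≈47 % move acceptance) the measured
mean is ≈ −19 kcal/mol.  The nominal block SEM (≈0.04) understates the
real uncertainty because successive snapshots, one accepted sweep apart,
are strongly correlated: independent seeds spread by a few tenths of a
kcal/mol.  The remaining distance to droplet-based estimates (≈ −18.5)
reflects the boundary-condition and measurement-convention substitutions
and sits well inside the ±1.5 kcal/mol band used for that quantity.

Detailed balance is checked on an 8-water box by Boltzmann-reweighting a
330 K run to 300 K and comparing mean energies with a direct 300 K run.

## Synthetic fixtures: what they show and what they do not

* The *tethered-water* generator draws oxygen positions from an isotropic
  Gaussian and orientations from a von Mises–Fisher distribution on unit
  quaternions (Wood's sampler), with Bernoulli per-frame occupancy;
  unoccupied frames park the water 500 Å away so atom counts stay fixed.
  Its ground truth is closed form (Gaussian translational entropy) or 1-D
  quadrature (orientational).  The orientational oracle subtracts ln 2 for
  water symmetry under the assumption of a well-separated mode; it is
  tabulated only for κ = 0 (exactly zero) or κ ≳ 15.  These ensembles have
  no solvent-solvent correlation, so recovering their entropies validates
  the estimators, not the first-order truncation itself.
* The *toy complex* is a randomized rigid receptor (20 charged LJ sites)
  with a small flexible ligand whose bonds, dihedral constants and charges
  are recorded, so every pipeline number is checkable by explicit double
  loops.  It validates bookkeeping (attribution, halving, additivity,
  block errors), not force-field realism.
* The *hydrogen-bond fixture* realizes exactly one direct and one bridging
  interaction under the default criteria (donor–acceptor ≤ 3.5 Å, D-H-A ≥
  120°; distance-only in heavy-atom mode).  Crystal-structure censuses are
  criteria-sensitive; the census operation therefore takes the criteria as
  parameters, and published interface counts are matched by scanning the
  distance cutoff over a small documented range.

## Degenerate inputs and tie-breaks

Alternate PDB locations keep the highest-occupancy conformer (first on
ties).  Waters are detected by a residue-name whitelist (HOH/WAT/TIP3/
TIP4/SPC/TP3), overridable per call.  Mainchain atoms are N/CA/C/O plus
chain-terminal variants and the hydrogens bonded to them; the
mainchain/sidechain split partitions every residue exactly.  Colinear
dihedrals, overlapping nonbonded groups, atoms closer than 1e-4 Å,
never-occupied sites, series shorter than the block count, and solutes
larger than their grid all raise typed errors rather than returning
numbers.  Dihedral energies in the per-residue decomposition are split
equally over the four dihedral atoms' groups; cross-group nonbonded pairs
are halved between the partners, which keeps group sums exactly equal to
whole-ligand values.

## Known limitations

* Published MD-scale binding numbers for the real polo-box system require
  the original multi-nanosecond trajectories and full force fields; the
  package reproduces the arithmetic and the desk-scale physics (bulk water
  enthalpy, closed-form oracles), not those ensemble averages.
* The PB solver is linear only; no membrane, no nonlinear Boltzmann term,
  no analytic molecular surfaces.
* First-order IFST only: water-water correlation entropy and
  occupancy-fluctuation terms are out of scope.
* The nearest-neighbour orientational estimator assumes unit quaternions
  from rigid 3-site waters; other solvent models would need their own
  symmetry number and reference geometry.
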