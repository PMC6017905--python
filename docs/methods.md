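# Methods

## The model

`tripmove` treats a polypeptide as an articulated mechanism under the
rigid-geometry assumption: bond lengths, bond angles and the peptide
torsion ω (fixed at 180°, trans) are constants; the backbone dihedrals
φ, ψ and the side-chain dihedrals χ are the only degrees of freedom.
Chains built from sequence use a single idealized geometry table
(Engh–Huber-like backbone values plus idealized side-chain placements,
stored as data in `tripmove/data/residue_geometry.yaml`); chains read
from PDB files keep their measured bond lengths and angles, rigid
thereafter.  Coordinates are in Å, angles in radians (degrees only at
file boundaries), and dihedrals follow the IUPAC sign convention
(cis = 0; this matches PDB practice).

Two virtual anchor atoms extend each chain end (a carbonyl carbon
before residue 1, an amide N/CA pair after the last residue), so every
residue carries a defined (φ, ψ) pair; the torsions that depend on a
virtual anchor are flagged as such.  Internal and Cartesian coordinates
are kept mutually consistent: every torsion edit either rebuilds all
downstream atoms (pivot semantics) or, for fixed-end moves, only the
atoms inside an explicit residue span whose far end is guaranteed by
loop closure.

The backbone maps onto a kinematic chain in the modified
Denavit–Hartenberg (mDH) convention: each joint contributes the
standard one-joint homogeneous transform with constant link offset,
twist and joint offset and a variable joint angle.  When every bond
torsion (φ, ψ, ω) is treated as a joint, consecutive joint axes
intersect at backbone atoms, so all link offsets `a` vanish; treating
the peptide bond as rigid absorbs the ω joint into a constant link.
mDH joint angles increase right-handed about the bond direction, which
is the opposite sense from IUPAC torsions; the fixed offset and sign
flip between the two is recorded once per joint.

## Tripeptide segmentation and particles

The chain is tiled into fragments of three residues (tripeptides) from
an explicit `start_offset` ∈ {0, 1, 2}; up to three leftover residues
at either end form terminal fragments parameterized directly by their
torsions.  Each tripeptide backbone carries six torsions — the
smallest fragment whose end frame has full 6-DOF mobility relative to
its base frame.  The oriented frame on the rigid peptide unit entering
a tripeptide's first residue is its *particle* (origin at N, z toward
CA, x referenced on the preceding carbonyl carbon).  Particle poses
plus tripeptide and terminal-fragment torsions determine every
backbone atom; `reconstruct_backbone` verifies this to ~1e-14 Å.

## The 6R inverse-kinematics solver

Closure of one tripeptide is the inverse kinematics of a general
6-revolute chain: find all θ₁..θ₆ with T₁(θ₁)…T₆(θ₆)·T_close equal to
a prescribed relative pose.  The solver exploits the structure every
tripeptide has — joint axes concurrent in pairs (φᵢ/ψᵢ meet at Cαᵢ).
Writing P₁, P₂, P₃ for the three intersection points, |P₁P₂| and
|P₂P₃| are configuration-invariant, P₁ is fixed by the base and P₃ is
recoverable from the target pose (it sits at a constant offset along
the last joint axis).  Closure then reduces to three scalar
constraints — the fixed angles between the axis pairs meeting at each
Pᵢ — in three rotations: σ (the rigid closure triangle about the
P₁–P₃ axis), τ₁ and τ₂ (spins of the two rigid units about the
virtual bonds P₁P₂ and P₂P₃).  Each constraint is bilinear in the
sines/cosines of exactly two variables: F₁(σ,τ₁), F₂(τ₁,τ₂), F₃(τ₂,σ).

Eliminating τ₁ and τ₂ with Sylvester resultants in the half-angle
tangents (coefficients obtained by exact small-grid interpolation of
batched determinants) leaves an eliminant h(σ) that is a trigonometric
polynomial of degree 8 — an algebraic polynomial of degree 16 in
z = e^{iσ}, matching the classical 16-solution bound for general 6R
chains.  Its coefficients come from a 32-point FFT of h; the roots are
the eigenvalues of the companion matrix.  For each unit-circle root,
back-substitution solves two 1-D trigonometric equations (≤2 branches
each), joint angles are reconstructed frame-by-frame from the solved
axis directions, and a Gauss–Newton polish on the full closure
equations drives each candidate to machine precision.  Every candidate
must independently pass a forward-kinematics residual check
(Frobenius norm < 1e-8); duplicates within 1e-6 rad merge, and the set
is canonically sorted by θ₁, making the solver deterministic.  Root
classification (|log|z|| < 1e-4) is only a pre-filter — the residual
is the ground truth for borderline roots.  Unreachable targets are
detected early by the triangle inequality on |P₁P₃| and reported as an
empty set, distinct from `IKNumericalError`, which signals degenerate
geometry (non-concurrent axis pairs, collinear closure triangle,
vanishing eliminant).  Chains without the concurrent-pair structure
are outside the solver's scope and raise that error.

Tangent half-angle parameterizations lose roots exactly at τ = π; the
azimuth references that define τ₁/τ₂ make that a measure-zero
coincidence for molecular geometry, and the Gauss–Newton continuation
path (below) provides an independent route to such solutions during
sampling.

### Continuation fast path

Monte Carlo moves perturb closure targets infinitesimally, so the
solution branch continuously connected to the current conformation is
(empirically always, for these step sizes) the closest solution that
the selection rule would pick.  The engine therefore first tracks that
branch by Gauss–Newton from the current joint angles (jitted with
numba) and falls back to the full eliminant solver whenever tracking
fails to deliver an in-threshold solution — so move availability is
identical to full enumeration, at a fraction of the cost.  On 500
seeded proposals the two routes select the same solution to 1e-9 rad
with no availability differences; near kinematic singularities (e.g.
fully extended strands) continuation may track a twin branch an
equally small distance away, which the tests bound explicitly.

## Move classes

All trial perturbations are drawn uniformly from [-δ, +δ].  Default
step sizes per class (δ_b = 0.01 rad pivot, 0.025 rad ConRot;
δ_pt = 0.05 Å, δ_pr = 0.003 rad one-particle; δ_pr = 0.01 rad hinge)
are the published settings for a ~70-residue globular test system and
are configurable per class.

* **OneTorsion (pivot)** — one random φ/ψ perturbed; all downstream
  atoms move by forward kinematics.
* **ConRot** — a driven torsion of residue r perturbed; the six
  torsions of residues r+1..r+3 (the immediately following three
  residues, regardless of decomposition alignment) are re-solved by IK
  so everything beyond stays fixed: exactly 7 torsions change.
* **OneParticle** — one particle pose perturbed (uniform random
  rotation axis, angle U(-δ_pr, δ_pr), componentwise translation
  U(-δ_pt, δ_pt)); the two flanking tripeptides re-solve: exactly 12
  consecutive torsions change.
* **FlexibleFragment** — n consecutive particles perturbed
  independently (optionally modulated along the fragment); n+1
  tripeptides re-solve, atomically (any failure discards the whole
  proposal).
* **Hinge** — a block of consecutive particles moved as one rigid
  body, rotated by U(-δ_pr, δ_pr) about a random axis through the
  segment joining the first and last block particle; only the two
  hinge tripeptides change torsions.  The sampled size n ∈ {3..10}
  counts the tripeptides whose atoms move (two hinges plus n-2
  transported rigidly), i.e. 3n residues — 9 to 30 — which fixes the
  rigid block at n-1 particles.
* **SideChain** — every χ of one random residue perturbed; the
  backbone is untouched.
* **Mixed** — one backbone class drawn per configurable weights
  (default: equal probability).

Failed proposals (IK failure, no in-threshold solution, clash,
Metropolis rejection) leave the chain bit-identical.  Fixed-end moves
rebuild only the atoms inside their span; the far junction's atoms are
kept exactly, with the closure residual (~1e-13) appearing as an
invisible geometric inconsistency far below the 1e-9 conservation
tolerance.  The closest-solution jump threshold defaults to 1.0 rad
on the Euclidean norm of wrapped angle differences — far beyond the
perturbation scale, so it only suppresses branch jumps.

## Clash filter and energy

A geometric filter runs before any energy call: a proposal is rejected
if any non-excluded pair involving a moved atom is closer than 70% of
its van der Waals equilibrium distance (sum of per-element radii from
an editable table of AMBER-type R_min/2 values).  1-2 and 1-3 bonded
pairs are excluded; 1-4 pairs participate by default (configurable).
Note that the *idealized* fully extended conformation genuinely fails
the filter (O(i)–CB(i+1) sits at 66% of the equilibrium distance);
helical and coil conformations pass.  A k-d-tree accelerates the
search for large systems and provably never changes the verdict; small
systems use a vectorized all-pairs check.

The default energy is deliberately simple and fully documented rather
than a force field: a 12-6 Lennard-Jones term
ε_ij[(r_eq/r)¹² − 2(r_eq/r)⁶] over non-excluded pairs (minimum −ε_ij
exactly at r_eq = R_i + R_j, pair depths geometric means of
per-element values) plus a generic three-fold torsional term
k_t(1 + cos 3θ), k_t = 0.2, over all variable torsions.  Energies are
in kcal/mol-consistent units; only differences over k_BT matter
(k_B = 0.0019872 kcal/mol/K).  Incremental evaluation over the moved
atoms agrees with full recomputation to better than 1e-6.  Any object
with `full(chain)`/`delta(chain, undo)` can replace it (e.g.
`TorsionPotential` for analytically integrable benchmarks).

## Monte Carlo engine

Each iteration chooses a backbone or side-chain move (probability 0.5
by default), generates a proposal, applies the clash filter, then the
Metropolis criterion min(1, e^{−ΔE/k_BT}) at T = 300 K by default.
All randomness flows through one seeded generator; identical
configuration and seed reproduce trajectories bit-exactly.  An
end-constraint freezes listed residues in position and orientation by
restricting move eligibility.  Strided conformation snapshots record
accepted states; dense observable series record the configuration
after *every* trial (duplicating the state on rejection), which is the
statistically correct ensemble for distribution tests and matches the
definition of the time series used for autocorrelation analysis.
Closest-solution selection without the Jacobian reweighting discussed
in the loop-closure literature is a known, documented bias of
fixed-end moves; the package exposes random and Boltzmann-weighted
selection as alternatives.

## Diagnostics

* Torsion-space RMSD with wrapped differences; rmsd(τ) as the
  full-overlap average of distances between states τ steps apart.
* acf(τ) by FFT with biased (1/n) normalization; τ_int = ½ + Σ acf(τ)
  with the automatic window that stops at the first m ≥ 5 τ_int.  The
  estimate is flagged non-converged when that window exceeds a fifth
  of the series: with the biased estimator the iteration always
  terminates formally, so window-to-length is the meaningful quality
  signal.  On AR(1) series of 1e6 points the estimator recovers
  ½ + ρ/(1−ρ) within 10% for ρ up to 0.9.
* Per-atom RMSF about the mean position, with frames least-squares
  superposed onto the first frame by default (otherwise rigid
  diffusion dominates; both modes are available), plus the cumulative
  RMSF over Cα atoms.

## The constrained-helix benchmark

The autocorrelation benchmark is an α-helical 14-alanine
(φ = −57°, ψ = −47°) whose terminal residues are blocked in position
and orientation, sampled without side-chain moves; the observables are
the 20 central dihedrals (φ/ψ of residues 3–12, 1-based).  The
decomposition uses start offset 1, which makes all three interior
particles usable under the end constraint.  The α-helical tripeptide
is kinematically ill-conditioned (smallest closure-Jacobian singular
value ≈ 0.035), so a substantial fraction of random particle
perturbations leave the reachable workspace; those IK failures count
as rejections, exactly as prescribed for fixed-end moves.

Step sizes for this system are not published; following the stated
calibration principle for meaningful class comparison — similar
average atom displacements, hence similar acceptance — ConRot keeps
δ_b = 0.025 rad and OneParticle uses δ_pt = 0.02 Å, δ_pr = 0.002 rad,
which matches the per-move mean displacement of moved atoms
(≈ 0.023 Å vs ≈ 0.025 Å) on this system; the uncalibrated globular
defaults give OneParticle 1.7× larger displacements with 4× lower
acceptance, invalidating the comparison.  `benchmarks.calibrate` (see
`move_class_comparison`) re-derives this.

## Scaled-down problem sizes

The package's own validation runs at desk scale: the double-well
Metropolis check uses 5 seeds × 2×10⁵ accepted samples, with the χ²
sample thinned at five times the estimated correlation time of the
well-occupancy indicator so the test's independence assumption holds;
the move-class comparison uses 3 seeds × 6×10⁴ trials per class.  At
these lengths the integrated autocorrelation times of the slowest
class (ConRot, τ_int ≳ 10⁴ trials) are truncation-limited and should
be read as lower bounds; the comparison tests the *ordering* of class
means, not their absolute values.

One caveat deserves emphasis: over the smooth default potential the
per-trial decorrelation rate of a move-class mixture is close to the
average of its components' rates, so the mixture's τ_int falls
*between* those of the individual classes.  The stronger behavior —
a mixture beating every individual class — arises from rugged
landscapes in which each class relieves bottlenecks the other cannot;
a simple Lennard-Jones + torsional surface has no such trapping, and
the mixture-beats-all ordering is accordingly not reliably reproduced
here (it is force-field-dependent, like the absolute autocorrelation
times).  What the benchmark does show robustly is OneParticle
decorrelating faster than ConRot and the full machinery (moves, IK,
estimators) operating correctly; what it does not show: force-field
specific acceptance rates, absolute autocorrelation times, or the
behavior of real side-chain-rich proteins.

## Known limitations

* No variable bond lengths/angles as degrees of freedom.  A bond-
  geometry relaxation pathway (perturbing a tripeptide's constant link
  parameters before solving IK) is compatible with the solver but not
  implemented: applying such solutions would require mutable
  per-residue geometry, which conflicts with the rigid-geometry
  conservation contract every invariant here tests.  No cis-proline
  entry ships in the default table (it would be a data entry, not
  code).
* The solver covers 6R chains with concurrent axis pairs — every
  rigid-geometry tripeptide, but not arbitrary manipulators.
* Single chains of standard residues only; a subset of side-chain
  types ships in the geometry table; hydrogens are not modeled.
* Strict canonical sampling of fixed-end moves would need the
  Jacobian detailed-balance correction; it is not implemented.
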