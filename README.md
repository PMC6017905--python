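# tripmove

Tripeptide-segmentation Monte Carlo sampling of protein backbones.

Devising good trial moves is the central difficulty in applying
Metropolis Monte Carlo to proteins: naive pivot moves displace half
the chain and are rejected in dense systems, while purely local moves
explore slowly.  `tripmove` implements a robotics-inspired answer: the
backbone is modeled as an articulated mechanism with rigid bond
geometry (only φ, ψ and side-chain χ torsions move) and segmented into
*tripeptides* — three-residue fragments whose six backbone torsions
form a general 6R kinematic chain, the smallest fragment with full
6-DOF mobility of its end frame.  An analytical inverse-kinematics
solver finds **all** conformations of a tripeptide compatible with
fixed end frames (at most 16, via elimination to a degree-16
polynomial solved as a companion-matrix eigenproblem), which turns
loop closure into a primitive that many move classes share:

* **OneTorsion** — classical pivot, one torsion + downstream rotation;
* **ConRot** — concerted rotation: a driven torsion compensated by
  re-solving the next tripeptide (7 torsions change, ends fixed);
* **OneParticle** — perturb the pose of one inter-tripeptide reference
  frame ("particle"); the two flanking tripeptides re-solve
  (12 torsions change);
* **FlexibleFragment** — n particles perturbed independently
  (n+1 tripeptides re-solve);
* **Hinge** — a block of particles moved as one rigid body, absorbed
  by the two hinge tripeptides;
* **Mixed** — a configurable mixture of the above.

A Metropolis engine runs these with a geometric clash filter (reject
non-bonded pairs closer than 70% of their van der Waals equilibrium
distance, checked before any energy call), a pluggable energy model
(a documented Lennard-Jones + torsional default ships with the
package), and exact seeded reproducibility.  The analysis module
provides the diagnostics used to compare move classes: torsion-space
RMSD, the time-dependent rmsd(τ), autocorrelation functions with the
integrated autocorrelation time τ_int = ½ + Σ_τ acf(τ) (truncated
self-consistently at 5 τ_int), and Cα RMSF.

See `docs/methods.md` for the model, the solver derivation, numerical
choices and known limitations.

## Worked example

```python
import numpy as np
from tripmove import build_chain_from_internal, decompose
from tripmove.moves import TripeptideSolver
from tripmove.decomposition import junction_frame
from tripmove.geometry import transform_inverse
from tripmove.ik import solve

n = 14
rng = np.random.default_rng(0)
chain = build_chain_from_internal("A" * n, rng.uniform(-2.5, -0.9, n),
                                  rng.uniform(-0.7, 2.5, n))
decomp = decompose(chain, start_offset=1)
print(decomp.n_tripeptides, len(decomp.n_term_fragment), len(decomp.c_term_fragment))
# -> 4 1 1    (14 residues = 1 + 4*3 + 1)

solver = TripeptideSolver(chain, first_res=1)
target = transform_inverse(junction_frame(chain, 1)) @ junction_frame(chain, 4)
sols = solve(solver.problem.with_target(target), reduction=solver.reduction)
print(sols.count, float(sols.residuals.max()))
# -> 8 4.9e-14
```

Eight distinct backbone conformations close this particular tripeptide
between its current end frames, each satisfying the loop-closure
equations to ~1e-14 (the current conformation is one of them); a
Monte Carlo move perturbs an end frame and picks the solution closest
to the previous state.  The `examples/` directory holds short
narrative scripts for each capability: building and decomposing
chains, enumerating IK solutions, running the sampler, the
constrained-helix autocorrelation benchmark, and PDB/trajectory I/O.

A thin command-line interface wraps the same machinery:

```sh
tripmove fixture --sequence AAAAAAAAAAAAAA --preset helix --out helix.pdb
tripmove run --config run.yaml --seed 1
tripmove analyze tau-int --traj out/trajectory_torsions.tsv
tripmove ik-selftest --n 1000 --seed 0
```

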