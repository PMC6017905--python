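"""Solve tripeptide loop closure with the analytical 6R solver.

Generates a reachable end-frame pose by forward kinematics from known
torsions, then asks the solver for *all* conformations that close the
loop.  The generating conformation always reappears among the
solutions; a 6R chain admits at most 16.
"""

import numpy as np

from tripmove.fixtures import build_polypeptide_fixture
from tripmove.geometry import wrap_angle
from tripmove.ik import closure_residual, solve
from tripmove.mdh import forward_kinematics
from tripmove.moves import TripeptideSolver

chain = build_polypeptide_fixture("AAAAA", "extended")
solver = TripeptideSolver(chain, first_res=1)

rng = np.random.default_rng(4)
thetas_true = rng.uniform(-np.pi, np.pi, 6)
links = [l.with_theta(t) for l, t in zip(solver.problem.links, thetas_true)]
target = forward_kinematics(links)[-1] @ solver.problem.t_close

problem = solver.problem.with_target(target)
sols = solve(problem, reduction=solver.reduction)
print(f"target generated from torsions (rad): {np.round(thetas_true, 3)}")
print(f"solver found {sols.count} closed conformations (bound: 16)")
for k, s in enumerate(sols):
    res = closure_residual(problem, s)
    dist = np.max(np.abs(wrap_angle(s - thetas_true)))
    tag = "  <- generating conformation" if dist < 1e-6 else ""
    print(f"  solution {k}: residual {res:.1e}, max |delta| to generator {dist:.2e}{tag}")

unreachable = np.eye(4)
unreachable[:3, 3] = [100.0, 0.0, 0.0]
print(f"unreachable target -> {solve(problem.with_target(unreachable), reduction=solver.reduction).count} solutions")
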