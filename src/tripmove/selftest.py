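"""Seeded property exercise of the 6R inverse-kinematics solver.

Generates reachable targets by forward kinematics from random torsion
sextuples on an idealized tripeptide, then checks that the solver
recovers the generating angles (completeness), that every returned
solution passes the independent closure-residual test (soundness), and
that no instance exceeds the theoretical bound of 16 solutions.
"""

from __future__ import annotations

import time

import numpy as np

from .fixtures import build_polypeptide_fixture
from .geometry import wrap_angle
from .ik import solve
from .mdh import forward_kinematics
from .moves import TripeptideSolver

__all__ = ["ik_selftest"]


def ik_selftest(n_problems: int = 1000, seed: int = 0, angle_tol: float = 1e-6) -> dict:
    """Run the solver on seeded FK-generated problems; returns statistics."""
    rng = np.random.default_rng(seed)
    chain = build_polypeptide_fixture("AAAAA", "extended")
    solver = TripeptideSolver(chain, 1)
    links = solver.problem.links
    t_close = solver.problem.t_close

    n_recovered = 0
    max_solutions = 0
    worst_residual = 0.0
    counts = []
    t0 = time.time()
    for _ in range(n_problems):
        thetas = rng.uniform(-np.pi, np.pi, 6)
        target = forward_kinematics([l.with_theta(t) for l, t in zip(links, thetas)])[-1] @ t_close
        sols = solve(solver.problem.with_target(target), reduction=solver.reduction)
        counts.append(sols.count)
        max_solutions = max(max_solutions, sols.count)
        if sols.count:
            worst_residual = max(worst_residual, float(sols.residuals.max()))
            best = min(np.max(np.abs(wrap_angle(s - thetas))) for s in sols)
            if best < angle_tol:
                n_recovered += 1
    elapsed = time.time() - t0
    return {
        "n_problems": n_problems,
        "n_recovered": n_recovered,
        "max_solutions": max_solutions,
        "worst_residual": worst_residual,
        "mean_solutions": float(np.mean(counts)),
        "mean_solve_ms": 1000.0 * elapsed / n_problems,
    }
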