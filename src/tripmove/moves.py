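"""Monte Carlo trial-move classes over the tripeptide representation.

Six proposal generators share one chain + decomposition:

* ``one_torsion_move`` — classical pivot: one phi/psi perturbed, the
  motion propagates to the chain end (no inverse kinematics).
* ``conrot_move`` — concerted rotation: a driven torsion is perturbed
  and the immediately following three residues are re-solved by IK so
  everything beyond them stays fixed (7 torsions change).
* ``one_particle_move`` — the pose of a single particle is perturbed
  and the two flanking tripeptides are re-solved (12 torsions).
* ``flexible_fragment_move`` — n consecutive particles perturbed
  independently; n+1 tripeptides re-solved.
* ``hinge_move`` — a block of n particles moved as one rigid body;
  only the two hinge tripeptides change conformation.
* ``side_chain_move`` — all chi angles of one residue perturbed.

Every generator returns a :class:`MoveProposal`; nothing touches the
chain until ``MoveProposal.apply`` runs, so a failed or rejected
proposal leaves the state bit-identical.  All perturbations are drawn
uniformly from ``[-delta, +delta]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import BackboneChain
from .decomposition import TripeptideDecomposition, junction_frame
from .geometry import make_transform, random_rotation, rotation_about_axis, transform_inverse, wrap_angle
from .ik import (IKNumericalError, IKProblem, _Reduction, select_solution, solve,
                 solve_continuation)
from .mdh import links_from_axes

__all__ = [
    "StepSizes",
    "MoveProposal",
    "TripeptideSolver",
    "one_torsion_move",
    "conrot_move",
    "one_particle_move",
    "flexible_fragment_move",
    "hinge_move",
    "side_chain_move",
    "mixed_move",
    "BACKBONE_CLASSES",
]

BACKBONE_CLASSES = ("OneTorsion", "ConRot", "OneParticle", "Hinge")


@dataclass(frozen=True)
class StepSizes:
    """Maximum perturbation amplitudes (drawn uniformly in [-d, +d]).

    ``delta_b``: bond torsion (rad); ``delta_pt``: particle translation
    (A); ``delta_pr``: particle rotation (rad).
    """

    delta_b: float = 0.025
    delta_pt: float = 0.05
    delta_pr: float = 0.003

    def __post_init__(self):
        if min(self.delta_b, self.delta_pt, self.delta_pr) < 0:
            raise ValueError("step sizes must be non-negative")


@dataclass
class MoveProposal:
    """A candidate conformational perturbation.

    ``updates`` maps torsion keys to proposed values; ``span`` is the
    residue range whose atoms are rebuilt on apply.  ``status`` is
    ``"ok"``, ``"ik_failed"`` (solver failed or found nothing) or
    ``"no_close_solution"`` (closest-selection threshold exceeded).
    """

    move_class: str
    status: str
    updates: dict = field(default_factory=dict)
    span: tuple[int, int] | None = None
    keep_end: bool = True

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def apply(self, chain: BackboneChain):
        """Mutate the chain; returns an undo record for ``chain.restore``."""
        if not self.ok:
            raise RuntimeError(f"cannot apply proposal with status {self.status!r}")
        if not self.updates:
            return chain.snapshot(0, 0)
        start, end = self.span
        return chain.apply_torsion_updates(self.updates, start, end, keep_end=self.keep_end)


class TripeptideSolver:
    """Cached IK machinery for the three residues starting at ``first_res``.

    The mDH link constants, closing transform and the torsion <-> joint
    angle offsets depend only on the rigid bond geometry, so one
    instance stays valid for a whole sampling run.
    """

    def __init__(self, chain: BackboneChain, first_res: int):
        r = first_res
        if r < 0 or r + 2 >= chain.n_residues + 1:
            raise ValueError("tripeptide out of range")
        self.first_res = r
        chain.refresh()
        base = junction_frame(chain, r)
        end = junction_frame(chain, r + 3)
        axes = []
        for i in (r, r + 1, r + 2):
            n_at = chain.coord(i, "N")
            ca = chain.coord(i, "CA")
            c = chain.coord(i, "C")
            axes.append((n_at, ca - n_at))
            axes.append((ca, c - ca))
        links, t_close = links_from_axes(base, axes, end)
        torsions = []
        for i in (r, r + 1, r + 2):
            torsions.extend((chain.phi[i], chain.psi[i]))
        # mDH joint angles increase right-handed about the bond
        # direction; IUPAC torsions have the opposite sense, so
        # theta_i = anchor_i - torsion_i with a constant anchor.
        self.anchor = wrap_angle(np.array([l.theta for l in links]) + np.asarray(torsions))
        self.problem = IKProblem(tuple(links), t_close, np.eye(4))
        self.reduction = _Reduction(self.problem)

    def torsion_keys(self):
        r = self.first_res
        return [(kind, i) for i in (r, r + 1, r + 2) for kind in ("phi", "psi")]

    def current_torsions(self, chain: BackboneChain) -> np.ndarray:
        r = self.first_res
        phi, psi = chain.phi, chain.psi
        return np.array([phi[r], psi[r], phi[r + 1], psi[r + 1], phi[r + 2], psi[r + 2]])

    def solve_torsions(self, base: np.ndarray, end: np.ndarray):
        """All torsion sextuples closing base -> end; None on failure."""
        target = transform_inverse(base) @ end
        try:
            sols = solve(self.problem.with_target(target), reduction=self.reduction)
        except IKNumericalError:
            return None
        if sols.count == 0:
            return None
        return wrap_angle(self.anchor - sols.solutions)

    def closest_update(self, chain, base, end, threshold, mode="enumerate"):
        """New torsion sextuple closing base -> end, picked by the
        closest-solution rule; ``(torsions | None, status)``.

        ``mode="enumerate"`` solves for all solutions and selects;
        ``mode="continuation"`` first tracks the branch connected to
        the current conformation — the closest solution for the small
        perturbations used in sampling, and much cheaper — and falls
        back to full enumeration whenever the tracking does not deliver
        an in-threshold solution, so move availability is identical in
        both modes.
        """
        current = self.current_torsions(chain)
        if mode == "continuation":
            target = transform_inverse(base) @ end
            theta0 = wrap_angle(self.anchor - current)
            theta = solve_continuation(self.problem.with_target(target), theta0)
            if theta is not None:
                tors = wrap_angle(self.anchor - theta)
                if np.linalg.norm(wrap_angle(tors - current)) <= threshold:
                    return tors, "ok"
        sols = self.solve_torsions(base, end)
        if sols is None:
            return None, "ik_failed"
        chosen = _closest(sols, current, threshold)
        if chosen is None:
            return None, "no_close_solution"
        return chosen, "ok"


def get_solver(cache: dict | None, chain: BackboneChain, first_res: int) -> TripeptideSolver:
    if cache is None:
        return TripeptideSolver(chain, first_res)
    solver = cache.get(first_res)
    if solver is None:
        solver = cache[first_res] = TripeptideSolver(chain, first_res)
    return solver


def _closest(torsion_sets: np.ndarray, current: np.ndarray, threshold: float):
    diffs = wrap_angle(torsion_sets - current)
    dists = np.linalg.norm(diffs, axis=1)
    best = int(np.argmin(dists))
    if dists[best] > threshold:
        return None
    return torsion_sets[best]


def _pivot_transform(chain: BackboneChain, kind: str, res: int, delta: float) -> np.ndarray:
    """World transform applied to everything downstream of a torsion
    when it increases by ``delta``."""
    if kind == "phi":
        p = chain.coord(res, "N")
        q = chain.coord(res, "CA")
    else:
        p = chain.coord(res, "CA")
        q = chain.coord(res, "C")
    rot = rotation_about_axis(q - p, -delta)
    return make_transform(rot, p - rot @ p)


# ---------------------------------------------------------------------------
# move generators
# ---------------------------------------------------------------------------


def pivot_candidates(chain: BackboneChain, frozen=frozenset()) -> list[int]:
    """Residues whose pivot rotation displaces no frozen residue
    (everything from the pivot to the C-terminus moves)."""
    n = chain.n_residues
    return [r for r in range(n) if all(x not in frozen for x in range(r, n))]


def conrot_candidates(chain: BackboneChain, frozen=frozenset()) -> list[int]:
    """Driven residues followed by a complete tripeptide, avoiding
    frozen residues in the affected span."""
    n = chain.n_residues
    return [r for r in range(n - 3) if all(x not in frozen for x in range(r, r + 4))]


def one_torsion_move(
    chain: BackboneChain,
    rng: np.random.Generator,
    delta_b: float,
    frozen: frozenset[int] = frozenset(),
    candidates: list[int] | None = None,
) -> MoveProposal:
    """Pivot move: one random phi/psi changed by U(-delta_b, delta_b),
    the motion propagating toward the C-terminal end of the chain."""
    n = chain.n_residues
    if candidates is None:
        candidates = pivot_candidates(chain, frozen)
    if not candidates:
        return MoveProposal("OneTorsion", "ik_failed")
    r = candidates[int(rng.integers(len(candidates)))]
    kind = "phi" if rng.integers(2) == 0 else "psi"
    delta = float(rng.uniform(-delta_b, delta_b))
    old = chain.phi[r] if kind == "phi" else chain.psi[r]
    return MoveProposal(
        "OneTorsion",
        "ok",
        updates={(kind, r): wrap_angle(old + delta)},
        span=(r, n - 1),
        keep_end=False,
    )


def conrot_move(
    chain: BackboneChain,
    decomp: TripeptideDecomposition | None,
    rng: np.random.Generator,
    delta_b: float,
    ik_cache: dict | None = None,
    closest_threshold: float = 1.0,
    frozen: frozenset[int] = frozenset(),
    candidates: list[int] | None = None,
    solver_mode: str = "enumerate",
) -> MoveProposal:
    """Concerted rotation: perturb one torsion of a residue, re-solve
    the immediately following tripeptide by IK to keep fixed ends."""
    if candidates is None:
        candidates = conrot_candidates(chain, frozen)
    if not candidates:
        return MoveProposal("ConRot", "ik_failed")
    r = candidates[int(rng.integers(len(candidates)))]
    kind = "phi" if rng.integers(2) == 0 else "psi"
    delta = float(rng.uniform(-delta_b, delta_b))

    chain.refresh()
    solver = get_solver(ik_cache, chain, r + 1)
    base = junction_frame(chain, r + 1)
    end = junction_frame(chain, r + 4)
    new_base = _pivot_transform(chain, kind, r, delta) @ base
    chosen, status = solver.closest_update(chain, new_base, end, closest_threshold, solver_mode)
    if chosen is None:
        return MoveProposal("ConRot", status)
    old = chain._phi[r] if kind == "phi" else chain._psi[r]
    updates = {(kind, r): wrap_angle(old + delta)}
    updates.update(dict(zip(solver.torsion_keys(), chosen)))
    return MoveProposal("ConRot", "ok", updates=updates, span=(r, r + 3), keep_end=True)


def _perturb_pose(pose: np.ndarray, rng: np.random.Generator, delta_pt: float, delta_pr: float) -> np.ndarray:
    """Random rigid perturbation: rotation about the frame origin by a
    random axis/angle plus a uniform translation of each component."""
    rot = random_rotation(rng, delta_pr) if delta_pr > 0 else np.eye(3)
    trans = rng.uniform(-delta_pt, delta_pt, 3) if delta_pt > 0 else np.zeros(3)
    origin = pose[:3, 3]
    perturb = make_transform(rot, origin - rot @ origin + trans)
    return perturb @ pose


def _particle_block_move(
    chain: BackboneChain,
    decomp: TripeptideDecomposition,
    tag: str,
    first_particle: int,
    new_poses: dict[int, np.ndarray],
    solved_tripeptides: list[int],
    ik_cache: dict | None,
    closest_threshold: float,
    solver_mode: str = "enumerate",
) -> MoveProposal:
    """Shared machinery: re-solve each tripeptide in
    ``solved_tripeptides`` between (possibly moved) junction poses."""
    chain.refresh()
    updates: dict = {}
    for k in solved_tripeptides:
        trip = decomp.tripeptides[k]
        solver = get_solver(ik_cache, chain, trip.first)
        base = new_poses.get(k)
        if base is None:
            base = junction_frame(chain, trip.first)
        end = new_poses.get(k + 1)
        if end is None:
            end = junction_frame(chain, trip.last + 1)
        chosen, status = solver.closest_update(chain, base, end, closest_threshold, solver_mode)
        if chosen is None:
            return MoveProposal(tag, status)
        updates.update(dict(zip(solver.torsion_keys(), chosen)))
    first = decomp.tripeptides[solved_tripeptides[0]].first
    last = decomp.tripeptides[solved_tripeptides[-1]].last
    return MoveProposal(tag, "ok", updates=updates, span=(first, last), keep_end=True)


def _interior_particles(decomp: TripeptideDecomposition, block: int, frozen) -> list[int]:
    """Start indices j such that particles j..j+block-1 have complete
    tripeptides on both sides and the affected span avoids frozen residues."""
    out = []
    for j in range(1, decomp.n_tripeptides - block + 1):
        first = decomp.tripeptides[j - 1].first
        last = decomp.tripeptides[j + block - 1].last
        if all(r not in frozen for r in range(first, last + 1)):
            out.append(j)
    return out


def one_particle_move(
    chain: BackboneChain,
    decomp: TripeptideDecomposition,
    rng: np.random.Generator,
    delta_pt: float,
    delta_pr: float,
    ik_cache: dict | None = None,
    closest_threshold: float = 1.0,
    frozen: frozenset[int] = frozenset(),
    candidates: list[int] | None = None,
    solver_mode: str = "enumerate",
) -> MoveProposal:
    """Perturb the pose of one particle; the two flanking tripeptides
    are re-solved, so at most 12 consecutive torsions change."""
    starts = _interior_particles(decomp, 1, frozen) if candidates is None else candidates
    if not starts:
        return MoveProposal("OneParticle", "ik_failed")
    k = starts[int(rng.integers(len(starts)))]
    chain.refresh()
    pose = junction_frame(chain, decomp.tripeptides[k].first)
    new_pose = _perturb_pose(pose, rng, delta_pt, delta_pr)
    return _particle_block_move(
        chain, decomp, "OneParticle", k, {k: new_pose}, [k - 1, k], ik_cache,
        closest_threshold, solver_mode
    )


def flexible_fragment_move(
    chain: BackboneChain,
    decomp: TripeptideDecomposition,
    rng: np.random.Generator,
    n_particles: int,
    delta_pt: float,
    delta_pr: float,
    ik_cache: dict | None = None,
    closest_threshold: float = 1.0,
    frozen: frozenset[int] = frozenset(),
    modulation=None,
    solver_mode: str = "enumerate",
) -> MoveProposal:
    """Perturb ``n_particles`` consecutive particles independently;
    the backbones of ``n_particles + 1`` tripeptides are re-solved.

    ``modulation`` optionally scales the step of each particle in the
    fragment (e.g. larger mid-fragment, smaller near the ends); it is
    a sequence of ``n_particles`` non-negative factors.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    starts = _interior_particles(decomp, n_particles, frozen)
    if not starts:
        return MoveProposal("FlexibleFragment", "ik_failed")
    j = starts[int(rng.integers(len(starts)))]
    factors = np.ones(n_particles) if modulation is None else np.asarray(modulation, float)
    chain.refresh()
    new_poses = {}
    for m in range(n_particles):
        k = j + m
        pose = junction_frame(chain, decomp.tripeptides[k].first)
        new_poses[k] = _perturb_pose(pose, rng, factors[m] * delta_pt, factors[m] * delta_pr)
    solved = list(range(j - 1, j + n_particles))
    return _particle_block_move(
        chain, decomp, "FlexibleFragment", j, new_poses, solved, ik_cache,
        closest_threshold, solver_mode
    )


def hinge_move(
    chain: BackboneChain,
    decomp: TripeptideDecomposition,
    rng: np.random.Generator,
    delta_pr: float,
    n_particles_range: tuple[int, int] = (3, 10),
    ik_cache: dict | None = None,
    closest_threshold: float = 1.0,
    frozen: frozenset[int] = frozenset(),
    solver_mode: str = "enumerate",
) -> MoveProposal:
    """Rigid-body block move: rotate a block of consecutive particles
    as one body about a random axis through the segment joining the
    first and last particle origins; only the two hinge tripeptides
    (before and after the block) change conformation.

    The move size ``n`` is drawn from ``n_particles_range`` (default
    3..10) and counts the tripeptides whose atoms move — two hinges
    plus ``n - 2`` rigidly transported ones, i.e. ``3 n`` residues —
    so the rigid block itself holds ``n - 1`` consecutive particles.
    """
    lo, hi = n_particles_range
    if lo < 3:
        raise ValueError("hinge size must be at least 3 (two hinges + one block tripeptide)")
    sizes = [n for n in range(lo, hi + 1) if _interior_particles(decomp, n - 1, frozen)]
    if not sizes:
        return MoveProposal("Hinge", "ik_failed")
    m = sizes[int(rng.integers(len(sizes)))] - 1
    starts = _interior_particles(decomp, m, frozen)
    j = starts[int(rng.integers(len(starts)))]
    chain.refresh()
    poses = {k: junction_frame(chain, decomp.tripeptides[k].first) for k in range(j, j + m)}
    p_first = poses[j][:3, 3]
    p_last = poses[j + m - 1][:3, 3]
    axis_dir = p_last - p_first
    if np.linalg.norm(axis_dir) < 1e-9:
        axis_dir = poses[j][:3, 2]
    pivot = p_first + rng.uniform(0.0, 1.0) * (p_last - p_first)
    rot = rotation_about_axis(axis_dir, float(rng.uniform(-delta_pr, delta_pr)))
    block_t = make_transform(rot, pivot - rot @ pivot)
    new_poses = {k: block_t @ pose for k, pose in poses.items()}
    # interior tripeptides keep their torsions: only the two hinge
    # tripeptides j-1 and j+m-1 are re-solved
    return _particle_block_move(
        chain, decomp, "Hinge", j, new_poses, [j - 1, j + m - 1], ik_cache,
        closest_threshold, solver_mode
    )


def side_chain_move(
    chain: BackboneChain,
    rng: np.random.Generator,
    delta_chi: float,
    frozen: frozenset[int] = frozenset(),
) -> MoveProposal:
    """Perturb every chi torsion of one randomly selected side chain.

    The backbone is untouched.  On chains without rotatable side
    chains the proposal is a no-op with status ``"ok"``.
    """
    candidates = [
        i for i in range(chain.n_residues) if chain.residues[i].n_chi > 0 and i not in frozen
    ]
    if not candidates:
        return MoveProposal("SideChain", "ok", updates={}, span=None)
    i = candidates[int(rng.integers(len(candidates)))]
    chi = chain.chi(i)
    updates = {
        ("chi", i, k): wrap_angle(chi[k] + rng.uniform(-delta_chi, delta_chi))
        for k in range(len(chi))
    }
    return MoveProposal("SideChain", "ok", updates=updates, span=(i, i), keep_end=True)


def mixed_move(
    chain: BackboneChain,
    decomp: TripeptideDecomposition,
    rng: np.random.Generator,
    weights: dict[str, float],
    step_sizes: StepSizes,
    ik_cache: dict | None = None,
    closest_threshold: float = 1.0,
    frozen: frozenset[int] = frozenset(),
    n_particles_range: tuple[int, int] = (3, 10),
    class_steps: dict[str, "StepSizes"] | None = None,
) -> MoveProposal:
    """Dispatch to one backbone move class drawn according to ``weights``
    (default usage: equal probability over the enabled classes).

    ``class_steps`` optionally overrides ``step_sizes`` per class,
    since calibrated step sizes differ between move classes.
    """
    names = list(weights)
    probs = np.array([weights[n] for n in names], float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("move-class weights must be non-negative and not all zero")
    probs = probs / probs.sum()
    choice = names[int(rng.choice(len(names), p=probs))]
    steps = class_steps.get(choice, step_sizes) if class_steps else step_sizes
    if choice == "OneTorsion":
        return one_torsion_move(chain, rng, steps.delta_b, frozen)
    if choice == "ConRot":
        return conrot_move(chain, decomp, rng, steps.delta_b, ik_cache,
                           closest_threshold, frozen)
    if choice == "OneParticle":
        return one_particle_move(chain, decomp, rng, steps.delta_pt,
                                 steps.delta_pr, ik_cache, closest_threshold, frozen)
    if choice == "Hinge":
        return hinge_move(chain, decomp, rng, steps.delta_pr, n_particles_range,
                          ik_cache, closest_threshold, frozen)
    if choice == "FlexibleFragment":
        n_p = int(rng.integers(1, 4))
        return flexible_fragment_move(chain, decomp, rng, n_p, steps.delta_pt,
                                      steps.delta_pr, ik_cache, closest_threshold, frozen)
    raise ValueError(f"unknown move class {choice!r}")
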