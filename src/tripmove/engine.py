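"""Metropolis Monte Carlo engine over backbone and side-chain moves.

Each iteration: choose backbone vs side-chain move, generate a
proposal, apply the geometric clash filter, then (if an energy model is
configured) evaluate the energy change and the Metropolis criterion
``min(1, exp(-dE/kT))``.  A proposal whose IK fails, whose clash test
fails or whose Metropolis draw fails is discarded atomically: the
chain state after a rejection is bit-identical to before the proposal.

All stochastic choices flow through a single seeded generator, so runs
are exactly reproducible from (configuration, seed).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .chain import BackboneChain
from .decomposition import TripeptideDecomposition, decompose
from .energy import ClashParams, ExclusionTable, clash_check
from .moves import StepSizes, side_chain_move

__all__ = ["KB", "MCConfig", "MCTrajectory", "metropolis_accept", "run",
           "build_constrained_helix_benchmark", "CENTRAL_DIHEDRALS_14ALA"]

KB = 0.0019872  # kcal/mol/K

# Table of default per-class step sizes: the values used for the
# globular-protein (SH3 domain) test system.
DEFAULT_CLASS_STEPS = {
    "OneTorsion": StepSizes(delta_b=0.01),
    "ConRot": StepSizes(delta_b=0.025),
    "OneParticle": StepSizes(delta_pt=0.05, delta_pr=0.003),
    "Hinge": StepSizes(delta_pr=0.01),
    "FlexibleFragment": StepSizes(delta_pt=0.05, delta_pr=0.003),
}


@dataclass
class MCConfig:
    """Run settings for the Monte Carlo engine.

    ``move_weights`` selects the enabled backbone classes; the default
    mixes the four standard classes with equal probability.  The
    ``frozen_residues`` end-constraint blocks the listed residues in
    position and orientation: no move is proposed that would displace
    any of their atoms.
    """

    temperature: float = 300.0
    backbone_prob: float = 0.5
    move_weights: dict[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in ("OneTorsion", "ConRot", "OneParticle", "Hinge")}
    )
    class_steps: dict[str, StepSizes] = field(default_factory=lambda: dict(DEFAULT_CLASS_STEPS))
    delta_chi: float = 0.1
    target_accepted: int = 10_000
    max_steps: int | None = None
    record_stride: int = 100
    seed: int = 0
    frozen_residues: tuple[int, ...] = ()
    start_offset: int = 0
    closest_threshold: float = 1.0
    hinge_range: tuple[int, int] = (3, 10)
    observable_keys: tuple = ()  # torsion keys recorded at every MC trial step
    record_ca: bool = True
    # "continuation" tracks the solution branch connected to the current
    # conformation (the closest solution for small steps, much faster);
    # "enumerate" always selects among all solutions
    solver_mode: str = "continuation"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.backbone_prob <= 1.0:
            raise ValueError("backbone_prob must be a probability")
        if any(w < 0 for w in self.move_weights.values()) or sum(self.move_weights.values()) <= 0:
            raise ValueError("move weights must be non-negative and not all zero")


@dataclass
class MCTrajectory:
    """Accepted-state records and per-class bookkeeping."""

    config: MCConfig
    step_indices: list = field(default_factory=list)  # MC step of each record
    torsions: list = field(default_factory=list)  # (phi, psi interleaved) per record
    chi: list = field(default_factory=list)
    ca_coords: list = field(default_factory=list)
    energies: list = field(default_factory=list)
    move_tags: list = field(default_factory=list)
    attempts: dict = field(default_factory=dict)
    accepts: dict = field(default_factory=dict)
    observables: np.ndarray | None = None  # (n_accepted, n_keys)
    n_accepted: int = 0
    n_steps: int = 0
    reached_target: bool = True

    @property
    def acceptance_rates(self) -> dict[str, float]:
        return {
            k: (self.accepts.get(k, 0) / n if n else 0.0)
            for k, n in self.attempts.items()
        }

    def torsion_array(self) -> np.ndarray:
        return np.asarray(self.torsions)

    def ca_array(self) -> np.ndarray:
        return np.asarray(self.ca_coords)


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE / kB T))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0.0:
        return True
    return rng.random() < np.exp(-delta_e / (KB * temperature))


def run(
    chain: BackboneChain,
    decomp: TripeptideDecomposition | None,
    config: MCConfig,
    energy_model=None,
    clash_params: ClashParams | None = None,
    log=None,
) -> MCTrajectory:
    """Run the Metropolis loop until ``target_accepted`` samples.

    ``energy_model`` is any object with ``full(chain)`` and
    ``delta(chain, undo)``; None disables the Metropolis test (pure
    geometric sampling).  ``clash_params`` None disables the overlap
    filter.  Returns a partial trajectory with ``reached_target=False``
    if the step cap is hit first.
    """
    rng = np.random.default_rng(config.seed)
    needs_decomp = any(c != "OneTorsion" for c in config.move_weights)
    if decomp is None and needs_decomp:
        decomp = decompose(chain, config.start_offset)
    chain.refresh()
    frozen = frozenset(config.frozen_residues)
    ik_cache: dict = {}
    exclusions = ExclusionTable(chain, clash_params.exclude_14) if clash_params else None

    traj = MCTrajectory(config=config)
    for name in list(config.move_weights) + ["SideChain"]:
        traj.attempts[name] = 0
        traj.accepts[name] = 0

    backbone_proposal = _Dispatcher(chain, decomp, config, ik_cache, frozen)
    energy = energy_model.full(chain) if energy_model is not None else 0.0
    obs_keys = list(config.observable_keys)
    # observables follow the state after every trial (the configuration
    # after the k-th trial, duplicated on rejection) — the statistically
    # meaningful series for Boltzmann checks and autocorrelation
    obs_buffer = np.empty((4096, len(obs_keys))) if obs_keys else None
    obs_idx = np.array(
        [(0 if kind == "phi" else 1, i) for kind, i in obs_keys], dtype=int
    ).reshape(-1, 2)

    max_steps = config.max_steps or 1000 * config.target_accepted
    has_side_chains = any(
        chain.residues[i].n_chi > 0 for i in range(chain.n_residues) if i not in frozen
    )
    t_start = time.time()
    step = 0
    while traj.n_accepted < config.target_accepted and step < max_steps:
        step += 1
        if config.backbone_prob < 1.0 and has_side_chains and rng.random() >= config.backbone_prob:
            proposal = side_chain_move(chain, rng, config.delta_chi, frozen)
        else:
            proposal = backbone_proposal(rng)
        traj.attempts[proposal.move_class] = traj.attempts.get(proposal.move_class, 0) + 1
        accepted = False
        if proposal.ok:
            undo = proposal.apply(chain)
            passed = True
            if clash_params is not None:
                passed, _ = clash_check(chain, clash_params, undo["atom_sel"], exclusions,
                                        use_grid=chain.n_atoms >= 400)
            if passed and energy_model is not None:
                delta_e = energy_model.delta(chain, undo)
                passed = metropolis_accept(delta_e, config.temperature, rng)
            if passed:
                accepted = True
                if energy_model is not None:
                    energy += delta_e
            else:
                chain.restore(undo)
        if obs_buffer is not None:
            if step > len(obs_buffer):
                obs_buffer = np.concatenate([obs_buffer, np.empty_like(obs_buffer)])
            row = np.where(obs_idx[:, 0] == 0, chain._phi[obs_idx[:, 1]], chain._psi[obs_idx[:, 1]])
            obs_buffer[step - 1] = row
        if not accepted:
            continue
        traj.n_accepted += 1
        traj.accepts[proposal.move_class] = traj.accepts.get(proposal.move_class, 0) + 1
        if traj.n_accepted % config.record_stride == 0 or traj.n_accepted == 1:
            traj.step_indices.append(step)
            traj.torsions.append(chain.torsion_vector())
            traj.chi.append([chain.chi(i) for i in range(chain.n_residues)])
            traj.energies.append(energy)
            traj.move_tags.append(proposal.move_class)
            if config.record_ca:
                traj.ca_coords.append(chain.ca_coords().copy())
        if log is not None and traj.n_accepted % 10_000 == 0:
            rates = ", ".join(f"{k}={v:.2f}" for k, v in traj.acceptance_rates.items() if traj.attempts[k])
            log(f"step {step}: accepted {traj.n_accepted}, rates {rates}, "
                f"{step / (time.time() - t_start):.0f} steps/s")

    traj.n_steps = step
    traj.reached_target = traj.n_accepted >= config.target_accepted
    if obs_buffer is not None:
        traj.observables = obs_buffer[:step]
    return traj


class _Dispatcher:
    """Pre-resolved move-class mixture: candidate lists and step sizes
    are computed once, since chain topology, decomposition and the
    end-constraint do not change during a run."""

    def __init__(self, chain, decomp, config, ik_cache, frozen):
        from . import moves as mv

        steps = {name: config.class_steps.get(name, StepSizes()) for name in config.move_weights}
        thr = config.closest_threshold
        mode = config.solver_mode
        gens = {}
        for name in config.move_weights:
            st = steps[name]
            if name == "OneTorsion":
                cand = mv.pivot_candidates(chain, frozen)
                gens[name] = lambda rng, st=st, c=cand: mv.one_torsion_move(
                    chain, rng, st.delta_b, frozen, candidates=c)
            elif name == "ConRot":
                cand = mv.conrot_candidates(chain, frozen)
                gens[name] = lambda rng, st=st, c=cand: mv.conrot_move(
                    chain, decomp, rng, st.delta_b, ik_cache, thr, frozen, candidates=c,
                    solver_mode=mode)
            elif name == "OneParticle":
                cand = mv._interior_particles(decomp, 1, frozen)
                gens[name] = lambda rng, st=st, c=cand: mv.one_particle_move(
                    chain, decomp, rng, st.delta_pt, st.delta_pr, ik_cache, thr, frozen,
                    candidates=c, solver_mode=mode)
            elif name == "Hinge":
                gens[name] = lambda rng, st=st: mv.hinge_move(
                    chain, decomp, rng, st.delta_pr, config.hinge_range, ik_cache, thr, frozen,
                    solver_mode=mode)
            elif name == "FlexibleFragment":
                gens[name] = lambda rng, st=st: mv.flexible_fragment_move(
                    chain, decomp, rng, int(rng.integers(1, 4)), st.delta_pt, st.delta_pr,
                    ik_cache, thr, frozen, solver_mode=mode)
            else:
                raise ValueError(f"unknown move class {name!r}")
        self.names = list(gens)
        self.gens = [gens[n] for n in self.names]
        w = np.array([config.move_weights[n] for n in self.names], float)
        self.cum = np.cumsum(w / w.sum())

    def __call__(self, rng):
        if len(self.gens) == 1:
            return self.gens[0](rng)
        i = int(np.searchsorted(self.cum, rng.random(), side="right"))
        return self.gens[min(i, len(self.gens) - 1)](rng)


CENTRAL_DIHEDRALS_14ALA = tuple(
    (kind, i) for i in range(2, 12) for kind in ("phi", "psi")
)


def ubiquitin_protocol(compare_class: str = "ConRot", **overrides) -> MCConfig:
    """Named preset for compact globular proteins: each iteration
    draws a side-chain perturbation with probability 75%, the compared
    backbone move class with 20%, or a pivot move with 5%.

    Realized as backbone probability 0.25 with backbone weights
    0.8/0.2 between the compared class and OneTorsion.
    """
    if compare_class not in ("ConRot", "OneParticle", "Hinge", "FlexibleFragment"):
        raise ValueError(f"unsupported compare class {compare_class!r}")
    kwargs = dict(
        backbone_prob=0.25,
        move_weights={compare_class: 0.8, "OneTorsion": 0.2},
    )
    kwargs.update(overrides)
    return MCConfig(**kwargs)


def build_constrained_helix_benchmark(
    n_res: int = 14,
    target_accepted: int = 100_000,
    move_weights: dict[str, float] | None = None,
    seed: int = 0,
    record_stride: int = 1000,
):
    """The constrained-helix autocorrelation benchmark system.

    An alpha-helical poly-alanine with both terminal residues blocked
    in position and orientation, so the chain only fluctuates around
    the helical state.  The constraint (and the small size) restricts
    the applicable move classes to ConRot, OneParticle and mixtures of
    the two; no side-chain moves are performed.  The 20 central
    dihedral angles (phi/psi of residues 3..12 in 1-based numbering)
    are recorded at every trial as the observables.

    Step sizes follow the calibration principle for comparable move
    classes — similar average atom displacement per move: ConRot keeps
    its published 0.025 rad, while OneParticle uses delta_pt = 0.02 A,
    delta_pr = 0.002 rad, which matches ConRot's mean moved-atom
    displacement on this system (see
    ``benchmarks.calibrate_one_particle_steps``).
    """
    from .fixtures import build_polypeptide_fixture

    chain = build_polypeptide_fixture("A" * n_res, "helix")
    decomp = decompose(chain, start_offset=1)
    if move_weights is None:
        move_weights = {"ConRot": 0.5, "OneParticle": 0.5}
    if not set(move_weights) <= {"ConRot", "OneParticle"}:
        raise ValueError("the constrained benchmark admits only ConRot and OneParticle moves")
    config = MCConfig(
        temperature=300.0,
        backbone_prob=1.0,
        move_weights=dict(move_weights),
        class_steps={
            "ConRot": StepSizes(delta_b=0.025),
            "OneParticle": StepSizes(delta_pt=0.02, delta_pr=0.002),
        },
        target_accepted=target_accepted,
        record_stride=record_stride,
        seed=seed,
        frozen_residues=(0, n_res - 1),
        start_offset=1,
        observable_keys=CENTRAL_DIHEDRALS_14ALA,
        record_ca=False,
    )
    return chain, decomp, config
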