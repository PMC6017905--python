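"""Canned benchmark protocols built on the engine and diagnostics.

The move-class comparison reproduces, at configurable scale, the
constrained 14-alanine experiment: for each enabled move class the
Metropolis loop runs on the end-blocked helix, the 20 central
dihedrals are recorded at every trial, and the integrated
autocorrelation time of each is estimated.  Mixing ConRot and
OneParticle is expected to decorrelate faster (smaller mean tau_int)
than the slower individual classes.
"""

from __future__ import annotations

import numpy as np

from .analysis import ObservableSeries, integrated_autocorrelation_time
from .energy import ClashParams, DefaultEnergy
from .engine import build_constrained_helix_benchmark, run

__all__ = ["MOVE_CLASS_MIXTURES", "move_class_comparison"]

MOVE_CLASS_MIXTURES = {
    "ConRot": {"ConRot": 1.0},
    "OneParticle": {"OneParticle": 1.0},
    "Mixed": {"ConRot": 0.5, "OneParticle": 0.5},
}


def mean_move_displacement(chain, decomp, generator, n_moves: int = 200, seed: int = 0) -> float:
    """Mean displacement of the moved atoms over successful proposals."""
    rng = np.random.default_rng(seed)
    chain.refresh()
    disps = []
    attempts = 0
    while len(disps) < n_moves and attempts < 100 * n_moves:
        attempts += 1
        prop = generator(rng)
        if not prop.ok:
            continue
        before = chain.coords.copy()
        undo = prop.apply(chain)
        d = np.linalg.norm(chain.coords - before, axis=1)
        moved = d[d > 0]
        disps.append(float(moved.mean()) if len(moved) else 0.0)
        chain.restore(undo)
    if not disps:
        raise RuntimeError("no successful proposals during calibration")
    return float(np.mean(disps))


def calibrate_one_particle_steps(delta_b: float = 0.025, scales=None, seed: int = 0):
    """Re-derive the benchmark's OneParticle step sizes.

    Following the calibration principle that move classes should
    produce average atom displacements of similar length, scan scale
    factors applied to the globular-system defaults (0.05 A, 0.003 rad)
    and return the (delta_pt, delta_pr) whose mean moved-atom
    displacement on the constrained 14-alanine helix is closest to
    ConRot's at the given ``delta_b``.
    """
    from .engine import build_constrained_helix_benchmark
    from .moves import conrot_move, one_particle_move

    chain, decomp, config = build_constrained_helix_benchmark(target_accepted=1, seed=seed)
    frozen = frozenset(config.frozen_residues)
    cache: dict = {}
    target = mean_move_displacement(
        chain, decomp,
        lambda rng: conrot_move(chain, decomp, rng, delta_b, ik_cache=cache, frozen=frozen),
        seed=seed,
    )
    if scales is None:
        scales = (0.1, 0.2, 0.4, 0.6, 0.8, 1.0)
    best = None
    for s in scales:
        pt, pr = 0.05 * s, 0.003 * s
        disp = mean_move_displacement(
            chain, decomp,
            lambda rng: one_particle_move(chain, decomp, rng, pt, pr, ik_cache=cache,
                                          frozen=frozen),
            seed=seed,
        )
        err = abs(disp - target)
        if best is None or err < best[0]:
            best = (err, pt, pr, disp)
    return {"delta_pt": best[1], "delta_pr": best[2],
            "displacement": best[3], "target_displacement": target}


def move_class_comparison(seed: int, n_trials: int = 100_000, mixtures=None, log=None) -> dict:
    """Mean/median tau_int of the 20 central dihedrals per move class.

    Returns ``{class: {"mean": .., "median": .., "acceptance": ..}}``
    for one seed, using ``n_trials`` Metropolis trials per class.
    """
    if mixtures is None:
        mixtures = MOVE_CLASS_MIXTURES
    out = {}
    for label, weights in mixtures.items():
        chain, decomp, config = build_constrained_helix_benchmark(
            target_accepted=2**31 - 1, seed=seed
        )
        config.move_weights = dict(weights)
        config.max_steps = n_trials
        traj = run(chain, decomp, config, energy_model=DefaultEnergy(chain),
                   clash_params=ClashParams(), log=log)
        taus = [
            integrated_autocorrelation_time(
                ObservableSeries(f"dihedral{j}", traj.observables[:, j])
            ).tau_int
            for j in range(traj.observables.shape[1])
        ]
        out[label] = {
            "mean": float(np.mean(taus)),
            "median": float(np.median(taus)),
            "max": float(np.max(taus)),
            "acceptance": traj.n_accepted / traj.n_steps,
            "n_trials": traj.n_steps,
        }
        if log is not None:
            log(f"{label}: mean tau_int {out[label]['mean']:.0f}, "
                f"median {out[label]['median']:.0f}")
    return out
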