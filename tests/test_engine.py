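import numpy as np
import pytest

from tripmove import build_chain_from_internal, decompose
from tripmove.energy import ClashParams, DefaultEnergy, TorsionPotential
from tripmove.engine import (
    CENTRAL_DIHEDRALS_14ALA,
    KB,
    MCConfig,
    build_constrained_helix_benchmark,
    metropolis_accept,
    run,
)
from tripmove.moves import StepSizes


def test_metropolis_downhill_and_zero_always_accept():
    rng = np.random.default_rng(0)
    assert all(metropolis_accept(-1.0, 300.0, rng) for _ in range(100))
    assert all(metropolis_accept(0.0, 300.0, rng) for _ in range(100))


def test_metropolis_frequency_matches_boltzmann_factor():
    """dE = kT ln 2 must be accepted with frequency 1/2 (3-sigma band
    over 1e5 seeded draws)."""
    rng = np.random.default_rng(1)
    t = 300.0
    de = KB * t * np.log(2.0)
    n = 100_000
    acc = sum(metropolis_accept(de, t, rng) for _ in range(n))
    sigma = np.sqrt(n * 0.25)
    assert abs(acc - n * 0.5) < 3 * sigma


def test_invalid_temperature_rejected():
    with pytest.raises(ValueError):
        metropolis_accept(1.0, 0.0, np.random.default_rng(0))
    with pytest.raises(ValueError):
        MCConfig(temperature=-10.0)


def _toy_setup(seed, target=2000):
    chain = build_chain_from_internal("A" * 6, [-1.0] * 6, [-0.8] * 6)
    cfg = MCConfig(
        temperature=300.0,
        backbone_prob=1.0,
        move_weights={"OneTorsion": 0.5, "ConRot": 0.5},
        class_steps={"OneTorsion": StepSizes(delta_b=0.1), "ConRot": StepSizes(delta_b=0.1)},
        target_accepted=target,
        max_steps=20 * target,
        record_stride=50,
        seed=seed,
        record_ca=True,
    )
    return chain, cfg


def test_same_seed_gives_bit_identical_trajectories():
    chain_a, cfg = _toy_setup(7, 500)
    traj_a = run(chain_a, None, cfg, energy_model=DefaultEnergy(chain_a),
                 clash_params=ClashParams())
    chain_b, cfg_b = _toy_setup(7, 500)
    traj_b = run(chain_b, None, cfg_b, energy_model=DefaultEnergy(chain_b),
                 clash_params=ClashParams())
    assert traj_a.n_steps == traj_b.n_steps
    assert np.array_equal(np.asarray(traj_a.torsions), np.asarray(traj_b.torsions))
    assert np.array_equal(chain_a.coords, chain_b.coords)
    assert traj_a.attempts == traj_b.attempts and traj_a.accepts == traj_b.accepts


def test_counter_conservation_and_record_monotonicity():
    chain, cfg = _toy_setup(3, 1000)
    traj = run(chain, None, cfg, energy_model=DefaultEnergy(chain), clash_params=ClashParams())
    assert traj.reached_target
    assert sum(traj.attempts.values()) == traj.n_steps
    assert sum(traj.accepts.values()) == traj.n_accepted == cfg.target_accepted
    for name in traj.attempts:
        assert traj.accepts.get(name, 0) <= traj.attempts[name]
    assert np.all(np.diff(traj.step_indices) > 0)
    # records follow the stride (first accepted state is also recorded)
    assert len(traj.torsions) == 1 + traj.n_accepted // cfg.record_stride


def test_infinite_temperature_accepts_everything_geometry_allows():
    chain, cfg = _toy_setup(5, 800)
    cfg.temperature = 1e12
    cfg.move_weights = {"OneTorsion": 1.0}
    traj = run(chain, None, cfg, energy_model=DefaultEnergy(chain), clash_params=None)
    assert traj.acceptance_rates["OneTorsion"] > 0.999


def test_step_cap_returns_partial_trajectory():
    chain, cfg = _toy_setup(9, 10_000)
    cfg.max_steps = 200
    traj = run(chain, None, cfg, energy_model=DefaultEnergy(chain), clash_params=ClashParams())
    assert not traj.reached_target
    assert traj.n_steps == 200


def test_energy_bookkeeping_consistent_with_full_recompute():
    chain, cfg = _toy_setup(11, 300)
    model = DefaultEnergy(chain)
    traj = run(chain, None, cfg, energy_model=model, clash_params=ClashParams())
    assert np.isclose(traj.energies[-1], model.full(chain), atol=1e-6)


def test_double_well_marginal_matches_boltzmann():
    """Release gate: on an analytically integrable two-torsion double
    well, the per-trial marginal of phi matches the numerically
    integrated Boltzmann density (chi-square, 20 bins)."""
    from scipy.stats import chisquare

    a_coef, b_coef = 1.5, 0.5
    pot = lambda t: a_coef * np.cos(2 * t) + b_coef * np.cos(t)
    chain = build_chain_from_internal("A", phi=[0.5], psi=[0.5])
    model = TorsionPotential({("phi", 0): pot, ("psi", 0): pot})
    cfg = MCConfig(
        temperature=300.0,
        backbone_prob=1.0,
        move_weights={"OneTorsion": 1.0},
        class_steps={"OneTorsion": StepSizes(delta_b=1.2)},
        target_accepted=60_000,
        record_stride=10**9,
        seed=2,
        observable_keys=(("phi", 0),),
        record_ca=False,
    )
    traj = run(chain, None, cfg, energy_model=model, clash_params=None)
    from tripmove.analysis import ObservableSeries, integrated_autocorrelation_time

    series = traj.observables[:, 0]
    # thin at 5x the correlation time of the slowest (well-hopping) mode
    tau = integrated_autocorrelation_time(
        ObservableSeries("well", (series < 0).astype(float))
    ).tau_int
    phi = series[:: max(50, int(np.ceil(5 * tau)))]
    kt = KB * 300.0
    edges = np.linspace(-np.pi, np.pi, 21)
    probs = np.array(
        [
            np.trapezoid(np.exp(-pot(np.linspace(a, b, 400)) / kt), np.linspace(a, b, 400))
            for a, b in zip(edges[:-1], edges[1:])
        ]
    )
    probs /= probs.sum()
    observed, _ = np.histogram(phi, edges)
    _, p = chisquare(observed, probs * len(phi))
    assert p > 0.01


def test_constrained_benchmark_blocks_end_residues():
    chain, decomp, cfg = build_constrained_helix_benchmark(target_accepted=300, seed=4)
    cfg.record_stride = 50
    frozen_atoms = np.where((chain.atom_res == 0) | (chain.atom_res == 13))[0]
    before = chain.coords[frozen_atoms].copy()
    traj = run(chain, decomp, cfg, energy_model=DefaultEnergy(chain),
               clash_params=ClashParams())
    assert traj.n_accepted == 300
    assert np.array_equal(chain.coords[frozen_atoms], before)


def test_constrained_benchmark_configuration():
    chain, decomp, cfg = build_constrained_helix_benchmark()
    assert set(cfg.move_weights) <= {"ConRot", "OneParticle"}
    assert cfg.backbone_prob == 1.0  # no side-chain moves
    assert len(cfg.observable_keys) == 20  # the 20 central dihedrals
    assert cfg.observable_keys == CENTRAL_DIHEDRALS_14ALA
    with pytest.raises(ValueError):
        build_constrained_helix_benchmark(move_weights={"Hinge": 1.0})


def test_ubiquitin_protocol_preset_probabilities():
    """The compact-globular preset draws side chain 75%, the compared
    class 20% and pivot 5% per iteration."""
    from tripmove.engine import ubiquitin_protocol

    cfg = ubiquitin_protocol("OneParticle")
    assert cfg.backbone_prob == 0.25
    w = cfg.move_weights
    total = sum(w.values())
    assert np.isclose(cfg.backbone_prob * w["OneParticle"] / total, 0.20)
    assert np.isclose(cfg.backbone_prob * w["OneTorsion"] / total, 0.05)
    with pytest.raises(ValueError):
        ubiquitin_protocol("SideChain")


def test_benchmark_step_sizes_balance_displacements():
    """The benchmark's OneParticle step sizes realize the calibration
    rule: mean moved-atom displacement per move matches ConRot's."""
    from tripmove import decompose
    from tripmove.benchmarks import mean_move_displacement
    from tripmove.engine import build_constrained_helix_benchmark
    from tripmove.moves import conrot_move, one_particle_move

    chain, decomp, cfg = build_constrained_helix_benchmark(target_accepted=1)
    frozen = frozenset(cfg.frozen_residues)
    cache = {}
    cr = cfg.class_steps["ConRot"]
    op = cfg.class_steps["OneParticle"]
    d_cr = mean_move_displacement(
        chain, decomp,
        lambda rng: conrot_move(chain, decomp, rng, cr.delta_b, ik_cache=cache, frozen=frozen),
        n_moves=80,
    )
    d_op = mean_move_displacement(
        chain, decomp,
        lambda rng: one_particle_move(chain, decomp, rng, op.delta_pt, op.delta_pr,
                                      ik_cache=cache, frozen=frozen),
        n_moves=80,
    )
    assert abs(d_op - d_cr) / d_cr < 0.25


def test_rejected_proposals_leave_state_bit_identical():
    """Run with an always-rejecting energy model: the chain never moves."""

    class RejectAll:
        def full(self, chain):
            return 0.0

        def delta(self, chain, undo):
            return 1e9

    chain, cfg = _toy_setup(13, 10)
    cfg.max_steps = 300
    before = chain.coords.copy()
    traj = run(chain, None, cfg, energy_model=RejectAll(), clash_params=None)
    assert traj.n_accepted == 0
    assert np.array_equal(chain.coords, before)
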