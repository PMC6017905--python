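import numpy as np
import pytest

from tripmove import decompose
from tripmove.fixtures import build_polypeptide_fixture
from tripmove.geometry import wrap_angle
from tripmove.moves import (
    StepSizes,
    conrot_move,
    flexible_fragment_move,
    hinge_move,
    mixed_move,
    one_particle_move,
    one_torsion_move,
    side_chain_move,
)


@pytest.fixture()
def coil30_setup(coil30):
    coil30.refresh()
    return coil30, decompose(coil30, 0), {}


def _torsion_diff_count(chain, before_tv):
    return int(np.sum(np.abs(wrap_angle(chain.torsion_vector() - before_tv)) > 0))


def _outside_displacement(chain, before_coords, span):
    outside = (chain.atom_res < span[0]) | (chain.atom_res > span[1])
    return float(np.max(np.linalg.norm(chain.coords[outside] - before_coords[outside], axis=1)))


def _exercise(chain, before_coords, before_tv, proposal):
    """Apply, measure, undo; returns (n_torsion_diffs, outside_disp, geom_dev)."""
    undo = proposal.apply(chain)
    n_diff = _torsion_diff_count(chain, before_tv)
    out = _outside_displacement(chain, before_coords, proposal.span)
    dev = chain.check_geometry()
    chain.restore(undo)
    assert np.array_equal(chain.coords, before_coords), "restore must be bit-exact"
    return n_diff, out, dev


def test_one_torsion_zero_step_is_identity(coil30_setup):
    chain, _, _ = coil30_setup
    prop = one_torsion_move(chain, np.random.default_rng(0), delta_b=0.0)
    (key, value), = prop.updates.items()
    old = chain.phi[key[1]] if key[0] == "phi" else chain.psi[key[1]]
    assert abs(wrap_angle(value - old)) < 1e-15


def test_one_torsion_bookkeeping(coil30_setup):
    """The proposed value equals old + drawn delta (wrapped), and the
    delta is bounded by delta_b."""
    chain, _, _ = coil30_setup
    rng = np.random.default_rng(5)
    for _ in range(20):
        prop = one_torsion_move(chain, rng, delta_b=0.3)
        (key, value), = prop.updates.items()
        old = chain.phi[key[1]] if key[0] == "phi" else chain.psi[key[1]]
        assert abs(wrap_angle(value - old)) <= 0.3 + 1e-12


def test_one_torsion_last_psi_moves_only_carbonyl(coil30):
    chain = coil30
    chain.refresh()
    n = chain.n_residues
    before = chain.coords.copy()
    undo = chain.apply_torsion_updates({("psi", n - 1): chain.psi[n - 1] + 0.5},
                                       n - 1, n - 1, keep_end=False)
    moved = np.where(np.any(chain.coords != before, axis=1))[0]
    assert list(moved) == [chain.atom_index(n - 1, "O")]
    chain.restore(undo)


def test_conrot_changes_exactly_seven_torsions(coil30_setup):
    chain, decomp, cache = coil30_setup
    rng = np.random.default_rng(8)
    before_c = chain.coords.copy()
    before_tv = chain.torsion_vector()
    seen = 0
    while seen < 10:
        prop = conrot_move(chain, decomp, rng, 0.1, ik_cache=cache)
        if not prop.ok:
            continue
        seen += 1
        n_diff, out, dev = _exercise(chain, before_c, before_tv, prop)
        assert n_diff == 7  # 1 driven + 6 compensating
        assert out == 0.0  # fixed ends, bit-exact
        assert dev < 1e-9


def test_conrot_zero_step_returns_current_conformation(coil30_setup):
    chain, decomp, cache = coil30_setup
    rng = np.random.default_rng(9)
    prop = conrot_move(chain, decomp, rng, 0.0, ik_cache=cache)
    assert prop.ok
    before_tv = chain.torsion_vector()
    undo = prop.apply(chain)
    assert np.max(np.abs(wrap_angle(chain.torsion_vector() - before_tv))) < 1e-10
    chain.restore(undo)


def test_one_particle_footprint_is_twelve_torsions(coil30_setup):
    chain, decomp, cache = coil30_setup
    rng = np.random.default_rng(10)
    before_c = chain.coords.copy()
    before_tv = chain.torsion_vector()
    seen = 0
    attempts = 0
    while seen < 8 and attempts < 500:
        attempts += 1
        prop = one_particle_move(chain, decomp, rng, 0.05, 0.003, ik_cache=cache)
        if not prop.ok:
            continue
        seen += 1
        n_diff, out, dev = _exercise(chain, before_c, before_tv, prop)
        assert n_diff == 12
        assert prop.span[1] - prop.span[0] + 1 == 6  # two flanking tripeptides
        assert out == 0.0
        assert dev < 1e-9
    assert seen == 8


def test_flexible_fragment_affects_n_plus_one_tripeptides(coil30_setup):
    chain, decomp, cache = coil30_setup
    rng = np.random.default_rng(11)
    before_c = chain.coords.copy()
    before_tv = chain.torsion_vector()
    seen = 0
    attempts = 0
    while seen < 5 and attempts < 800:
        attempts += 1
        prop = flexible_fragment_move(chain, decomp, rng, 3, 0.03, 0.002, ik_cache=cache)
        if not prop.ok:
            continue
        seen += 1
        n_diff, out, dev = _exercise(chain, before_c, before_tv, prop)
        assert n_diff <= 4 * 6  # n+1 tripeptides
        assert out == 0.0 and dev < 1e-9
    assert seen == 5


def test_flexible_fragment_n1_equals_one_particle_span(coil30_setup):
    chain, decomp, cache = coil30_setup
    rng = np.random.default_rng(12)
    prop = flexible_fragment_move(chain, decomp, rng, 1, 0.0, 0.0, ik_cache=cache)
    assert prop.ok
    assert prop.span[1] - prop.span[0] + 1 == 6


def test_flexible_fragment_zero_deltas_identity(coil30_setup):
    chain, decomp, cache = coil30_setup
    prop = flexible_fragment_move(chain, decomp, np.random.default_rng(1), 2, 0.0, 0.0,
                                  ik_cache=cache)
    assert prop.ok
    before_tv = chain.torsion_vector()
    undo = prop.apply(chain)
    assert np.max(np.abs(wrap_angle(chain.torsion_vector() - before_tv))) < 1e-10
    chain.restore(undo)


def test_hinge_rigidity_and_two_tripeptide_footprint(coil30_setup):
    """Block particles keep their pairwise transforms to 1e-12; only
    the two hinge tripeptides change torsions."""
    from tripmove.decomposition import junction_frame
    from tripmove.geometry import transform_inverse

    chain, decomp, cache = coil30_setup
    rng = np.random.default_rng(13)
    before_c = chain.coords.copy()
    before_tv = chain.torsion_vector()
    seen = 0
    attempts = 0
    while seen < 5 and attempts < 800:
        attempts += 1
        prop = hinge_move(chain, decomp, rng, 0.02, (3, 6), ik_cache=cache)
        if not prop.ok:
            continue
        seen += 1
        # block tripeptides strictly inside the span keep their torsions
        first_trip = decomp.tripeptide_of_residue(prop.span[0])
        last_trip = decomp.tripeptide_of_residue(prop.span[1])
        block = [k for k in range(first_trip.index + 1, last_trip.index)]
        poses_before = {
            k: junction_frame(chain, decomp.tripeptides[k].first) for k in block
        }
        rel_before = {
            k: transform_inverse(poses_before[block[0]]) @ poses_before[k] for k in block
        }
        undo = prop.apply(chain)
        n_diff = _torsion_diff_count(chain, before_tv)
        assert n_diff == 12  # exactly two tripeptides re-solved
        poses_after = {
            k: junction_frame(chain, decomp.tripeptides[k].first) for k in block
        }
        for k in block[1:]:
            rel_after = transform_inverse(poses_after[block[0]]) @ poses_after[k]
            assert np.max(np.abs(rel_after - rel_before[k])) < 1e-12
        assert _outside_displacement(chain, before_c, prop.span) == 0.0
        assert chain.check_geometry() < 1e-9
        chain.restore(undo)
    assert seen == 5


def test_hinge_span_matches_sampled_size(coil30_setup):
    chain, decomp, cache = coil30_setup
    rng = np.random.default_rng(14)
    for _ in range(30):
        prop = hinge_move(chain, decomp, rng, 0.01, (3, 3), ik_cache=cache)
        if prop.ok:
            assert prop.span[1] - prop.span[0] + 1 == 9  # 3 tripeptides = 9 residues
            return
    pytest.skip("no successful hinge in 30 attempts")


def test_side_chain_move_leaves_backbone_fixed(mixed_chain):
    chain = mixed_chain
    chain.refresh()
    rng = np.random.default_rng(15)
    before = chain.coords.copy()
    bb = chain.backbone_indices()
    for _ in range(10):
        prop = side_chain_move(chain, rng, 0.4)
        assert prop.ok
        undo = prop.apply(chain)
        assert np.array_equal(chain.coords[bb], before[bb])
        # chi changes confined to one residue
        changed_res = {key[1] for key in prop.updates}
        assert len(changed_res) == 1
        chain.restore(undo)


def test_side_chain_move_zero_step_identity(mixed_chain):
    prop = side_chain_move(mixed_chain, np.random.default_rng(0), 0.0)
    i = next(iter(prop.updates))[1]
    assert np.allclose(
        [v for k, v in sorted(prop.updates.items())], mixed_chain.chi(i), atol=1e-15
    )


def test_side_chain_move_no_rotatable_chains_is_noop():
    chain = build_polypeptide_fixture("GAGA", "extended")
    prop = side_chain_move(chain, np.random.default_rng(0), 0.3)
    assert prop.ok and not prop.updates


def test_mixed_degenerate_weights_always_one_class(coil30_setup):
    chain, decomp, cache = coil30_setup
    rng = np.random.default_rng(16)
    for _ in range(20):
        prop = mixed_move(chain, decomp, rng, {"OneTorsion": 1.0, "ConRot": 0.0,
                                               "OneParticle": 0.0, "Hinge": 0.0},
                          StepSizes(), ik_cache=cache)
        assert prop.move_class == "OneTorsion"


def test_mixed_uniform_weights_frequencies(coil30_setup):
    chain, decomp, cache = coil30_setup
    rng = np.random.default_rng(17)
    weights = {c: 0.25 for c in ("OneTorsion", "ConRot", "OneParticle", "Hinge")}
    counts = {c: 0 for c in weights}
    n = 10_000
    for _ in range(n):
        prop = mixed_move(chain, decomp, rng, weights, StepSizes(delta_pt=0.0, delta_pr=0.0,
                                                                delta_b=0.0), ik_cache=cache)
        assert prop.move_class in weights
        counts[prop.move_class] += 1
    sigma = np.sqrt(n * 0.25 * 0.75)
    for c, k in counts.items():
        assert abs(k - n * 0.25) < 3 * sigma, (c, k)


def test_mixed_rejects_bad_weights(coil30_setup):
    chain, decomp, _ = coil30_setup
    with pytest.raises(ValueError):
        mixed_move(chain, decomp, np.random.default_rng(0), {"OneTorsion": 0.0}, StepSizes())


def test_step_size_scaling_monotonic(coil30_setup):
    """Mean atom displacement per successful ConRot move grows with
    the step size (the calibration rationale)."""
    chain, decomp, cache = coil30_setup
    before = chain.coords.copy()
    means = []
    for delta in (0.001, 0.01, 0.1):
        rng = np.random.default_rng(99)
        disps = []
        attempts = 0
        while len(disps) < 15 and attempts < 600:
            attempts += 1
            prop = conrot_move(chain, decomp, rng, delta, ik_cache=cache)
            if not prop.ok:
                continue
            undo = prop.apply(chain)
            disps.append(np.mean(np.linalg.norm(chain.coords - before, axis=1)))
            chain.restore(undo)
        means.append(np.mean(disps))
    assert means[0] < means[1] < means[2]


def test_frozen_residues_never_selected(coil30_setup):
    chain, decomp, cache = coil30_setup
    frozen = frozenset({0, 1, 2, 27, 28, 29})
    rng = np.random.default_rng(20)
    for _ in range(50):
        prop = mixed_move(chain, decomp, rng,
                          {c: 0.25 for c in ("OneTorsion", "ConRot", "OneParticle", "Hinge")},
                          StepSizes(), ik_cache=cache, frozen=frozen)
        if prop.ok and prop.span is not None:
            assert prop.span[0] > 2 and prop.span[1] < 27
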