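import numpy as np
import pytest

from tripmove.fixtures import build_polypeptide_fixture
from tripmove.geometry import wrap_angle
from tripmove.ik import (
    IKNumericalError,
    IKProblem,
    IKSolutionSet,
    closure_residual,
    select_solution,
    solve,
)
from tripmove.mdh import MDHLink, forward_kinematics
from tripmove.moves import TripeptideSolver


@pytest.fixture(scope="module")
def tripeptide_problem():
    chain = build_polypeptide_fixture("AAAAA", "extended")
    solver = TripeptideSolver(chain, 1)
    return solver


def _fk_target(solver, thetas):
    links = [l.with_theta(t) for l, t in zip(solver.problem.links, thetas)]
    return forward_kinematics(links)[-1] @ solver.problem.t_close


def test_fk_generated_targets_are_recovered(tripeptide_problem):
    """Completeness: the generating sextuple always appears among the
    solutions (to 1e-6 rad), every solution is sound (< 1e-8 residual)
    and the count never exceeds 16."""
    solver = tripeptide_problem
    rng = np.random.default_rng(42)
    for _ in range(150):
        thetas = rng.uniform(-np.pi, np.pi, 6)
        problem = solver.problem.with_target(_fk_target(solver, thetas))
        sols = solve(problem, reduction=solver.reduction)
        assert 1 <= sols.count <= 16
        assert sols.residuals.max() < 1e-8
        for s in sols:
            assert closure_residual(problem, s) < 1e-8
        best = min(np.max(np.abs(wrap_angle(s - thetas))) for s in sols)
        assert best < 1e-6


def test_unreachable_target_returns_empty_set(tripeptide_problem):
    solver = tripeptide_problem
    target = np.eye(4)
    target[:3, 3] = [100.0, 0.0, 0.0]  # beyond total chain extent
    sols = solve(solver.problem.with_target(target), reduction=solver.reduction)
    assert sols.count == 0


def test_solver_is_deterministic_and_sorted(tripeptide_problem):
    solver = tripeptide_problem
    rng = np.random.default_rng(3)
    target = _fk_target(solver, rng.uniform(-np.pi, np.pi, 6))
    a = solve(solver.problem.with_target(target), reduction=solver.reduction)
    b = solve(solver.problem.with_target(target), reduction=solver.reduction)
    assert np.array_equal(a.solutions, b.solutions)
    assert np.all(np.diff(a.solutions[:, 0]) >= 0)


def test_degenerate_geometry_raises_numerical_error():
    # consecutive parallel joint axes: no concurrent-pair structure
    links = tuple(
        MDHLink(a_prev=1.0, alpha_prev=0.0, d=0.0, theta=0.0) for _ in range(6)
    )
    with pytest.raises(IKNumericalError):
        solve(IKProblem(links, np.eye(4), np.eye(4)))


def test_solutions_wrapped_to_principal_interval(tripeptide_problem):
    solver = tripeptide_problem
    rng = np.random.default_rng(9)
    target = _fk_target(solver, rng.uniform(-np.pi, np.pi, 6))
    sols = solve(solver.problem.with_target(target), reduction=solver.reduction)
    assert np.all(sols.solutions > -np.pi) and np.all(sols.solutions <= np.pi)


# -- solution selection ---------------------------------------------------


def _solution_set(rows):
    rows = np.asarray(rows, float)
    return IKSolutionSet(rows, np.zeros(len(rows)))


def test_closest_returns_exact_current_at_zero_distance():
    current = np.array([0.1, -0.2, 0.3, 1.0, -1.0, 2.0])
    sols = _solution_set([current, current + 0.5])
    picked = select_solution(sols, current, "closest", threshold=1.0)
    assert np.array_equal(picked, current)


def test_closest_ordering_and_threshold():
    current = np.zeros(6)
    near = np.full(6, 0.1 / np.sqrt(6))  # norm 0.1
    far = np.full(6, 2.0 / np.sqrt(6))  # norm 2.0
    sols = _solution_set([far, near])
    assert np.array_equal(select_solution(sols, current, "closest", threshold=1.0), near)
    sols_far = _solution_set([far])
    assert select_solution(sols_far, current, "closest", threshold=1.0) is None


def test_closest_uses_wrapped_distance():
    current = np.full(6, np.pi - 0.01)
    wrapped_near = np.full(6, -np.pi + 0.01)  # 0.02 away through the cut
    naive_near = np.full(6, np.pi - 1.0)
    sols = _solution_set([naive_near, wrapped_near])
    picked = select_solution(sols, current, "closest", threshold=0.5)
    assert np.array_equal(picked, wrapped_near)


def test_random_selection_is_uniform():
    """Empirical frequencies over 1e4 draws on a 4-solution set stay
    within 3 sigma of the binomial expectation."""
    rng = np.random.default_rng(11)
    rows = np.arange(24, dtype=float).reshape(4, 6)
    sols = _solution_set(rows)
    counts = np.zeros(4)
    n = 10_000
    for _ in range(n):
        picked = select_solution(sols, rows[0], "random", rng=rng)
        counts[int(picked[0]) // 6] += 1
    p = 0.25
    sigma = np.sqrt(n * p * (1 - p))
    assert np.all(np.abs(counts - n * p) < 3 * sigma)


def test_boltzmann_weighting_prefers_low_energy():
    rng = np.random.default_rng(13)
    rows = np.zeros((2, 6))
    rows[1] += 1.0
    sols = _solution_set(rows)
    energy = lambda s: 0.0 if s[0] < 0.5 else 3.0
    picks = [
        select_solution(sols, rows[0], "boltzmann_weighted", rng=rng, energy_fn=energy, kt=1.0)[0]
        for _ in range(2000)
    ]
    frac_low = np.mean(np.asarray(picks) < 0.5)
    expected = 1.0 / (1.0 + np.exp(-3.0))
    assert abs(frac_low - expected) < 0.04


def test_empty_set_signals_rejection():
    empty = IKSolutionSet(np.empty((0, 6)), np.empty(0))
    assert select_solution(empty, np.zeros(6), "closest") is None
    assert select_solution(empty, np.zeros(6), "random", rng=np.random.default_rng(0)) is None


def test_continuation_agrees_with_enumeration():
    """Dual route: branch tracking and full enumeration + closest
    selection pick the same solution (or both reject) for perturbed
    closure targets on a regular conformation."""
    from tripmove import build_chain_from_internal
    from tripmove.decomposition import junction_frame
    from tripmove.moves import _perturb_pose

    n = 8
    chain = build_chain_from_internal("A" * n, [-1.0] * n, [-0.8] * n)
    solver = TripeptideSolver(chain, 1)
    base = junction_frame(chain, 1)
    end = junction_frame(chain, 4)
    rng = np.random.default_rng(21)
    for _ in range(100):
        nb = _perturb_pose(base, rng, 0.05, 0.01)
        a, _ = solver.closest_update(chain, nb, end, 1.0, "enumerate")
        b, _ = solver.closest_update(chain, nb, end, 1.0, "continuation")
        assert (a is None) == (b is None)
        if a is not None:
            assert np.max(np.abs(wrap_angle(a - b))) < 1e-9


def test_continuation_near_singular_stays_in_threshold(tripeptide_problem):
    """On a near-singular (extended) tripeptide two solution branches
    almost coincide; continuation may then track the twin branch, but
    it must still deliver a sound, in-threshold solution essentially
    as close as the enumerated optimum."""
    from tripmove.decomposition import junction_frame
    from tripmove.moves import _perturb_pose

    chain = build_polypeptide_fixture("AAAAA", "extended")
    solver = TripeptideSolver(chain, 1)
    base = junction_frame(chain, 1)
    end = junction_frame(chain, 4)
    current = solver.current_torsions(chain)
    rng = np.random.default_rng(21)
    for _ in range(100):
        nb = _perturb_pose(base, rng, 0.05, 0.01)
        a, _ = solver.closest_update(chain, nb, end, 1.0, "enumerate")
        b, _ = solver.closest_update(chain, nb, end, 1.0, "continuation")
        assert (a is None) == (b is None)
        if a is None:
            continue
        d_enum = np.linalg.norm(wrap_angle(a - current))
        d_cont = np.linalg.norm(wrap_angle(b - current))
        assert d_cont <= 1.0
        assert d_cont <= d_enum + 0.15
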