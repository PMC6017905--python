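import numpy as np
import pytest

from tripmove.analysis import (
    ObservableSeries,
    acf_function,
    autocorrelation,
    distance_energy,
    integrated_autocorrelation_time,
    rmsf,
    time_dependent_rmsd,
    torsion_rmsd,
)
from tripmove.geometry import wrap_angle


def _ar1(rho, n, seed):
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed)
    noise = rng.normal(size=n)
    return lfilter([1.0], [1.0, -rho], noise)


# -- torsion distance -----------------------------------------------------


def test_torsion_rmsd_identity_is_zero():
    q = np.array([0.3, -1.2, 2.9])
    assert torsion_rmsd(q, q) == 0.0


def test_torsion_rmsd_single_pi_difference_closed_form():
    for n in (1, 4, 9):
        a = np.zeros(n)
        b = np.zeros(n)
        b[0] = np.pi
        assert np.isclose(torsion_rmsd(a, b), np.pi / np.sqrt(n), atol=1e-12)


def test_torsion_rmsd_wraps_angles():
    a = np.array([np.deg2rad(359.0)])
    b = np.array([np.deg2rad(1.0)])
    assert np.isclose(torsion_rmsd(a, b), np.deg2rad(2.0), atol=1e-12)


def test_torsion_rmsd_topology_mismatch():
    with pytest.raises(ValueError):
        torsion_rmsd(np.zeros(3), np.zeros(4))


# -- time-dependent rmsd --------------------------------------------------


def test_rmsd_tau_zero_lag_and_constant_trajectory():
    q = np.tile(np.array([0.1, 0.7, -0.4]), (50, 1))
    vals = time_dependent_rmsd(q, 10)
    assert np.allclose(vals, 0.0)
    assert vals[0] == 0.0


def test_rmsd_tau_matches_brute_force_double_loop():
    rng = np.random.default_rng(5)
    q = rng.uniform(-np.pi, np.pi, size=(100, 7))
    tau_max = 30
    vals = time_dependent_rmsd(q, tau_max)
    for tau in range(1, tau_max + 1):
        ref = np.mean([torsion_rmsd(q[k], q[k + tau]) for k in range(len(q) - tau)])
        assert abs(vals[tau] - ref) < 1e-12


def test_rmsd_tau_invariant_under_reversal():
    rng = np.random.default_rng(6)
    q = rng.uniform(-np.pi, np.pi, size=(80, 5))
    assert np.allclose(time_dependent_rmsd(q, 20), time_dependent_rmsd(q[::-1], 20), atol=1e-12)


def test_rmsd_tau_rejects_excessive_lag():
    with pytest.raises(ValueError):
        time_dependent_rmsd(np.zeros((10, 3)), 10)


# -- autocorrelation ------------------------------------------------------


def test_acf_normalization_and_bounds():
    series = ObservableSeries("x", _ar1(0.7, 20_000, 1))
    acf = acf_function(series, 100)
    assert np.isclose(acf[0], 1.0)
    assert np.all(acf <= 1.0 + 1e-9) and np.all(acf >= -1.0 - 1e-9)
    assert autocorrelation(series, 0) == pytest.approx(1.0)


def test_acf_constant_series_raises():
    with pytest.raises(ValueError):
        acf_function(ObservableSeries("c", np.ones(100)))


def test_acf_matches_ar1_closed_form():
    """acf(tau) of an AR(1) process equals rho^tau."""
    rho = 0.9
    series = ObservableSeries("ar1", _ar1(rho, 1_000_000, 2))
    acf = acf_function(series, 20)
    for tau in range(1, 21):
        assert abs(acf[tau] - rho**tau) < 0.01


def test_acf_white_noise_within_noise_floor():
    n = 100_000
    series = ObservableSeries("wn", _ar1(0.0, n, 3))
    acf = acf_function(series, 50)
    assert np.all(np.abs(acf[1:]) < 3.0 / np.sqrt(n))


def test_acf_matches_statsmodels():
    """Independent oracle: statsmodels' FFT estimator (same biased
    normalization)."""
    sm = pytest.importorskip("statsmodels.tsa.stattools")
    x = _ar1(0.8, 5000, 4)
    ours = acf_function(ObservableSeries("x", x), 40)
    theirs = sm.acf(x, nlags=40, fft=True, adjusted=False)
    assert np.allclose(ours, theirs, atol=1e-8)


# -- integrated autocorrelation time -------------------------------------


def test_tau_int_white_noise_is_half():
    r = integrated_autocorrelation_time(ObservableSeries("wn", _ar1(0.0, 200_000, 5)))
    assert r.converged
    assert abs(r.tau_int - 0.5) < 0.05


@pytest.mark.parametrize("rho", [0.5, 0.8, 0.9])
def test_tau_int_matches_ar1_closed_form(rho):
    """tau_int of AR(1) equals 1/2 + rho/(1-rho) within 10%."""
    expected = 0.5 + rho / (1.0 - rho)
    r = integrated_autocorrelation_time(ObservableSeries("ar1", _ar1(rho, 1_000_000, 6)))
    assert r.converged
    assert abs(r.tau_int - expected) / expected < 0.10


def test_tau_int_monotone_in_correlation():
    taus = [
        integrated_autocorrelation_time(ObservableSeries("x", _ar1(rho, 400_000, 7))).tau_int
        for rho in (0.5, 0.8, 0.95)
    ]
    assert taus[0] < taus[1] < taus[2]


def test_tau_int_flags_series_shorter_than_correlation_time():
    # a random walk is correlated on the scale of the whole series;
    # the truncation window then spans a large fraction of it
    rng = np.random.default_rng(8)
    walk = np.cumsum(rng.normal(size=2000))
    r = integrated_autocorrelation_time(ObservableSeries("rw", walk))
    assert not r.converged
    assert r.window > len(walk) / 5


def test_tau_int_applies_stride():
    x = _ar1(0.8, 100_000, 9)
    a = integrated_autocorrelation_time(ObservableSeries("x", x, stride=1))
    b = integrated_autocorrelation_time(ObservableSeries("x", x, stride=10))
    assert np.isclose(b.tau_int, 10 * a.tau_int)


# -- RMSF -----------------------------------------------------------------


def test_rmsf_static_trajectory_is_zero():
    frames = np.tile(np.random.default_rng(0).normal(size=(5, 3)), (10, 1, 1))
    per_atom, cumulative = rmsf(frames, superpose=False)
    assert np.allclose(per_atom, 0.0, atol=1e-12)
    assert cumulative < 1e-12


def test_rmsf_two_point_alternation_closed_form():
    d = 0.75
    frames = np.zeros((20, 2, 3))
    frames[1::2, 0, 0] = 2 * d  # atom 0 alternates between x=0 and x=2d
    frames[:, 1] = [5.0, 5.0, 5.0]  # static anchor atom
    per_atom, _ = rmsf(frames, superpose=False)
    assert np.isclose(per_atom[0], d, atol=1e-12)
    assert per_atom[1] == 0.0


def test_rmsf_matches_two_pass_oracle():
    rng = np.random.default_rng(10)
    frames = rng.normal(size=(50, 8, 3))
    per_atom, cumulative = rmsf(frames, superpose=False)
    mean = frames.mean(axis=0)
    ref = np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))
    assert np.allclose(per_atom, ref, atol=1e-12)
    assert np.isclose(cumulative, ref.sum())


def test_rmsf_superposition_removes_rigid_drift():
    """A rigidly translating body has zero internal fluctuation; only
    the superposed estimate sees that."""
    rng = np.random.default_rng(11)
    body = rng.normal(size=(6, 3))
    frames = np.stack([body + [0.1 * t, 0.0, 0.0] for t in range(30)])
    per_drift, _ = rmsf(frames, superpose=False)
    per_fit, _ = rmsf(frames, superpose=True)
    assert np.all(per_fit < 1e-9)
    assert np.all(per_drift > 0.1)


def test_rmsf_rejects_empty_or_single_frame():
    with pytest.raises(ValueError):
        rmsf(np.zeros((1, 4, 3)))
    with pytest.raises(ValueError):
        rmsf(np.zeros((5, 0, 3)))


def test_distance_energy_projection_shapes():
    rng = np.random.default_rng(12)

    class Traj:
        energies = list(rng.normal(size=20))

        def torsion_array(self):
            return rng.uniform(-np.pi, np.pi, size=(20, 6))

    d, e = distance_energy(Traj())
    assert len(d) == 20 and len(e) == 20
    assert d[0] == 0.0
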