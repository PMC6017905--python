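"""Diagnostics for comparing Monte Carlo move classes.

* ``torsion_rmsd`` — conformational distance in torsion space (rad),
  with proper angle wrapping (359 deg vs 1 deg count as 2 deg apart).
* ``time_dependent_rmsd`` — rmsd(tau): average distance between states
  separated by tau MC steps; measures short-term exploration speed.
* ``autocorrelation`` / ``integrated_autocorrelation_time`` — acf(tau)
  of a scalar observable and tau_int = 1/2 + sum acf(tau), the
  effective decorrelation scale, with the summation truncated
  self-consistently at 5 tau_int.
* ``rmsf`` — per-atom root mean square fluctuation about the mean
  position, plus its cumulative sum over atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import wrap_angle

__all__ = [
    "ObservableSeries",
    "torsion_rmsd",
    "time_dependent_rmsd",
    "autocorrelation",
    "acf_function",
    "TauIntResult",
    "integrated_autocorrelation_time",
    "rmsf",
    "distance_energy",
]


@dataclass
class ObservableSeries:
    """Scalar observations indexed by MC step, with sampling stride."""

    name: str
    values: np.ndarray
    stride: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"series {self.name!r} contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


def _torsion_matrix(traj) -> np.ndarray:
    if hasattr(traj, "torsion_array"):
        return traj.torsion_array()
    return np.asarray(traj, float)


def torsion_rmsd(q_a, q_b) -> float:
    """Root mean square deviation of bond torsions between two
    conformations of the same topology (rad, wrapped differences)."""
    a = np.asarray(q_a, float)
    b = np.asarray(q_b, float)
    if a.shape != b.shape:
        raise ValueError(f"topology mismatch: {a.shape} vs {b.shape} torsions")
    d = wrap_angle(a - b)
    return float(np.sqrt(np.mean(d * d)))


def time_dependent_rmsd(traj, tau_max: int) -> np.ndarray:
    """rmsd(tau) for tau = 0..tau_max (in recorded-state units).

    Averages ``torsion_rmsd(q_k, q_{k+tau})`` over all valid k (the
    full-overlap estimator).
    """
    q = _torsion_matrix(traj)
    n = len(q)
    if tau_max >= n:
        raise ValueError(f"tau_max {tau_max} >= trajectory length {n}")
    out = np.zeros(tau_max + 1)
    for tau in range(1, tau_max + 1):
        d = wrap_angle(q[tau:] - q[:-tau])
        out[tau] = np.mean(np.sqrt(np.mean(d * d, axis=1)))
    return out


def acf_function(series: ObservableSeries, max_lag: int | None = None) -> np.ndarray:
    """Normalized autocorrelation acf(0..max_lag) via FFT.

    Uses the biased (1/n) normalization, the standard stable choice for
    integrated-autocorrelation-time estimation.  Raises on a constant
    series (undefined variance).
    """
    x = series.values - series.values.mean()
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    var = float(np.mean(x * x))
    if var == 0.0:
        raise ValueError("constant series: autocorrelation undefined")
    if max_lag is None:
        max_lag = n - 1
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1] / n
    return acov / var


def autocorrelation(series: ObservableSeries, tau: int) -> float:
    """acf at a single lag; acf(0) == 1 for any non-constant series."""
    return float(acf_function(series, max_lag=tau)[tau])


@dataclass
class TauIntResult:
    tau_int: float  # in MC steps (stride applied)
    window: int  # truncation lag actually used (in series units)
    converged: bool


def integrated_autocorrelation_time(series: ObservableSeries) -> TauIntResult:
    """Self-consistently truncated tau_int = 1/2 + sum acf(tau).

    The summation window grows until it first satisfies
    ``window >= 5 * tau_int`` (automatic windowing).  The estimate is
    flagged non-converged when the resulting window is not small
    compared to the series (more than a fifth of its length): the
    biased acf forces the sum to terminate eventually even for series
    much shorter than their correlation time, and such estimates are
    not trustworthy.
    """
    acf = acf_function(series)
    n = len(acf)
    tau = 0.5
    csum = np.cumsum(acf[1:])
    for m in range(1, n):
        tau = 0.5 + csum[m - 1]
        if m >= 5.0 * tau:
            return TauIntResult(
                tau_int=tau * series.stride, window=m, converged=m <= (n - 1) / 5
            )
    return TauIntResult(tau_int=tau * series.stride, window=n - 1, converged=False)


def rmsf(frames, superpose: bool = True):
    """Per-atom RMSF (A) and its cumulative sum.

    ``frames``: (n_frames, n_atoms, 3) coordinates, or an object with
    ``ca_array()``.  With ``superpose=True`` every frame is first
    least-squares superposed onto the first frame, removing rigid-body
    drift; fluctuations are then measured about the mean position.
    """
    if hasattr(frames, "ca_array"):
        frames = frames.ca_array()
    x = np.asarray(frames, float)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("need at least two frames of (n_atoms, 3) coordinates")
    if x.shape[1] == 0:
        raise ValueError("empty atom selection")
    if superpose:
        from .geometry import superpose as _sp

        ref = x[0]
        x = np.stack([_sp(fr, ref)[0] for fr in x])
    mean = x.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))
    return per_atom, float(per_atom.sum())


def distance_energy(traj, reference=None):
    """(torsion distance to reference, energy) pairs for the
    distance-vs-energy projection of sampled states."""
    q = _torsion_matrix(traj)
    e = np.asarray(traj.energies, float) if hasattr(traj, "energies") else None
    ref = q[0] if reference is None else np.asarray(reference, float)
    d = np.array([torsion_rmsd(ref, row) for row in q])
    return d, e
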