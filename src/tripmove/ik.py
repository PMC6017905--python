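"""Analytical inverse kinematics for tripeptide-class 6R chains.

Problem: given six revolute joints described by constant mDH parameters
and a constant closing transform, find all torsion sextuples
``(theta_1 .. theta_6)`` with ``T1 T2 T3 T4 T5 T6 . t_close == target``.

The solver exploits the structure every tripeptide backbone has: joint
axes come in concurrent pairs — (1,2) meet at the first C-alpha, (3,4)
at the second, (5,6) at the third.  Writing ``P1, P2, P3`` for the
three intersection points, the distances ``|P1 P2|`` and ``|P2 P3|``
are configuration-independent, so closure reduces to three scalar
constraints in three rotation variables:

* ``sigma``  — rotation of the rigid triangle (P1, P2, P3) about the
  anchor axis P1-P3 (both endpoints are fixed by base and target pose);
* ``tau_1``  — spin of the rigid unit carrying axes 2 and 3 about the
  virtual bond P1-P2;
* ``tau_2``  — spin of the unit carrying axes 4 and 5 about P2-P3.

Each constraint fixes the angle between two joint axes that meet at a
P-point and is bilinear in the sines/cosines of exactly two variables:
``F1(sigma, tau_1)``, ``F2(tau_1, tau_2)``, ``F3(tau_2, sigma)``.
Eliminating ``tau_1`` and ``tau_2`` with Sylvester resultants in the
half-angle tangents leaves a trigonometric polynomial ``h(sigma)`` of
degree 8, i.e. an algebraic polynomial of degree 16 in
``z = exp(i sigma)`` — matching the classical bound of 16 solutions
for a general 6R chain.  Its roots come from the eigenvalues of the
companion matrix; back-substitution, sequential frame reconstruction
and a Gauss-Newton polish yield machine-precision torsion sextuples.
Every candidate must pass an independent forward-kinematics residual
check (Frobenius norm < 1e-8) before it is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import line_intersection, transform_inverse, wrap_angle
from .mdh import MDHLink, forward_kinematics, mdh_transform

__all__ = [
    "IKProblem",
    "IKSolutionSet",
    "IKNumericalError",
    "solve",
    "select_solution",
    "closure_residual",
]

_RESIDUAL_TOL = 1e-8
_MERGE_TOL = 1e-6

# trig basis (1, cos, sin) -> polynomial in u = tan(angle/2), ascending
# powers, after multiplying through by (1 + u^2)
_TRIG_TO_POLY = np.array([[1.0, 0.0, 1.0], [1.0, 0.0, -1.0], [0.0, 2.0, 0.0]])

_U2_NODES = np.cos(np.pi * (2 * np.arange(5) + 1) / 10.0)  # Chebyshev, 5 points
_VAND_INV = np.linalg.inv(np.vander(_U2_NODES, 5, increasing=True))

_N_SIGMA = 32  # FFT samples; h has trig degree <= 8


class IKNumericalError(RuntimeError):
    """Solver failure distinct from 'no solution exists'."""


@dataclass(frozen=True)
class IKProblem:
    """A 6R loop-closure instance.

    ``links`` carry the constant mDH geometry (their ``theta`` values
    are only used as the reference configuration for extracting the
    invariant geometric quantities).  ``target`` is the required pose
    of the end frame relative to the base: solutions satisfy
    ``T1 .. T6 . t_close == target``.
    """

    links: tuple[MDHLink, ...]
    t_close: np.ndarray
    target: np.ndarray

    def __post_init__(self):
        if len(self.links) != 6:
            raise ValueError("a 6R problem needs exactly six links")

    def with_target(self, target: np.ndarray) -> "IKProblem":
        return IKProblem(self.links, self.t_close, target)


@dataclass
class IKSolutionSet:
    """All real solutions, canonically ordered by theta_1."""

    solutions: np.ndarray  # (n, 6), wrapped to (-pi, pi]
    residuals: np.ndarray  # (n,)

    @property
    def count(self) -> int:
        return len(self.solutions)

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self):
        return iter(self.solutions)


def closure_residual(problem: IKProblem, thetas) -> float:
    """Independent forward-kinematics check of a candidate solution."""
    links = [l.with_theta(t) for l, t in zip(problem.links, thetas)]
    achieved = forward_kinematics(links)[-1] @ problem.t_close
    return float(np.linalg.norm(achieved - problem.target))


def _rx(alpha: float) -> np.ndarray:
    c, s = np.cos(alpha), np.sin(alpha)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rz(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class _Reduction:
    """Configuration-invariant geometry extracted from a 6R problem."""

    def __init__(self, problem: IKProblem):
        links = problem.links
        frames = forward_kinematics(links)
        axes_p = [f[:3, 3] for f in frames[1:]]
        axes_z = [f[:3, 2] for f in frames[1:]]
        try:
            p1 = line_intersection(axes_p[0], axes_z[0], axes_p[1], axes_z[1])
            p2 = line_intersection(axes_p[2], axes_z[2], axes_p[3], axes_z[3])
            p3 = line_intersection(axes_p[4], axes_z[4], axes_p[5], axes_z[5])
        except ValueError as exc:
            raise IKNumericalError(
                f"joint axes lack the concurrent-pair tripeptide structure: {exc}"
            ) from exc

        self.alphas = np.array([l.alpha_prev for l in links])
        self.t_close_inv = transform_inverse(problem.t_close)

        # anchors: P1 is rigid w.r.t. the base; P3 sits at a constant
        # offset along the last joint axis, recoverable from any target
        self.p1 = p1
        self.z1 = axes_z[0]
        self.p3_offset = float(axes_z[5] @ (p3 - axes_p[5]))

        self.l1 = float(np.linalg.norm(p2 - p1))
        self.l2 = float(np.linalg.norm(p3 - p2))
        if self.l1 < 1e-9 or self.l2 < 1e-9:
            raise IKNumericalError("degenerate tripeptide: coincident C-alpha points")

        # cone angles at the three joints pairs
        self.c1 = float(axes_z[0] @ axes_z[1])
        self.c2 = float(axes_z[2] @ axes_z[3])
        self.c3 = float(axes_z[4] @ axes_z[5])

        # cylindrical coordinates of axes 2,3 about edge P1->P2 and of
        # axes 4,5 about edge P2->P3 (invariant unit-body constants)
        self.u1_cyl = self._cylindrical(p1, p2, axes_z[1], axes_z[2])
        self.u2_cyl = self._cylindrical(p2, p3, axes_z[3], axes_z[4])

    @staticmethod
    def _cylindrical(pa, pb, z_first, z_second):
        e = (pb - pa) / np.linalg.norm(pb - pa)
        par_f = float(z_first @ e)
        perp_f = z_first - par_f * e
        rho_f = float(np.linalg.norm(perp_f))
        par_s = float(z_second @ e)
        perp_s = z_second - par_s * e
        rho_s = float(np.linalg.norm(perp_s))
        if rho_f < 1e-9 or rho_s < 1e-9:
            raise IKNumericalError("joint axis parallel to virtual bond: unsupported geometry")
        nf = perp_f / rho_f
        ns = perp_s / rho_s
        # signed azimuth of the second axis relative to the first
        delta = float(np.arctan2(_cross3(nf, ns) @ e, nf @ ns))
        return par_f, rho_f, par_s, rho_s, delta


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3-vector cross product without numpy's generic-axis overhead."""
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _unit_perp(v: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to v."""
    a = np.zeros(3)
    a[np.argmin(np.abs(v))] = 1.0
    w = _cross3(v, a)
    return w / np.linalg.norm(w)


def _axis_vectors(par, rho, delta, e, nu, mu):
    """Basis vectors of z(tau) = V0 + cos(tau) V1 + sin(tau) V2."""
    cd, sd = np.cos(delta), np.sin(delta)
    v0 = par * e
    v1 = rho * (cd * nu + sd * mu)
    v2 = rho * (-sd * nu + cd * mu)
    return v0, v1, v2


class _WorldSetup:
    """Target-dependent world geometry and trig coefficient matrices."""

    def __init__(self, red: _Reduction, problem: IKProblem):
        self.red = red
        end = problem.target @ red.t_close_inv
        self.end_rot = end[:3, :3]
        self.z6 = end[:3, 2]
        p3 = end[:3, 3] + red.p3_offset * self.z6
        self.p3 = p3
        d = p3 - red.p1
        self.l3 = float(np.linalg.norm(d))
        self.feasible = True
        if self.l3 < 1e-9:
            raise IKNumericalError("anchor points coincide: triangle axis undefined")
        cos_b1 = (red.l1**2 + self.l3**2 - red.l2**2) / (2.0 * red.l1 * self.l3)
        cos_b2 = (red.l1**2 + red.l2**2 - self.l3**2) / (2.0 * red.l1 * red.l2)
        if abs(cos_b1) > 1.0 or abs(cos_b2) > 1.0:
            self.feasible = False  # triangle inequality violated: unreachable
            return
        sin_b1 = np.sqrt(max(0.0, 1.0 - cos_b1**2))
        sin_b2 = np.sqrt(max(0.0, 1.0 - cos_b2**2))
        if sin_b1 < 1e-9 or sin_b2 < 1e-9:
            # collinear triangle: a measure-zero tangency configuration
            raise IKNumericalError("degenerate (collinear) closure triangle")
        self.ez = d / self.l3
        self.g = _unit_perp(self.ez)
        self.gy = np.cross(self.ez, self.g)
        self.cos_b1, self.sin_b1 = float(cos_b1), float(sin_b1)
        self.cos_b2, self.sin_b2 = float(cos_b2), float(sin_b2)

        # trig coefficient matrices M[j, k]: F = t_j(a) M[j,k] t_k(b)
        # with basis t = (1, cos, sin); a = sigma for F1/F3.
        self._fit_matrices()

    # -- world geometry at a given sigma ------------------------------

    def triangle(self, sigma: float):
        """World positions/edge frames of the closure triangle."""
        red = self.red
        u = np.cos(sigma) * self.g + np.sin(sigma) * self.gy
        p2 = red.p1 + red.l1 * (self.cos_b1 * self.ez + self.sin_b1 * u)
        e1 = (p2 - red.p1) / red.l1
        nu1 = (self.ez - self.cos_b1 * e1) / self.sin_b1
        mu1 = _cross3(e1, nu1)
        e2 = (self.p3 - p2) / red.l2
        v = (red.p1 - p2) / red.l1
        nu2 = (v - self.cos_b2 * e2) / self.sin_b2
        mu2 = _cross3(e2, nu2)
        return p2, (e1, nu1, mu1), (e2, nu2, mu2)

    def axis_z(self, sigma: float, tau1: float, tau2: float):
        """World directions of joint axes 2..5 for given angles."""
        red = self.red
        _, (e1, nu1, mu1), (e2, nu2, mu2) = self.triangle(sigma)
        par2, rho2, par3, rho3, d23 = red.u1_cyl
        par4, rho4, par5, rho5, d45 = red.u2_cyl
        z2 = _axis_vectors(par2, rho2, 0.0, e1, nu1, mu1)
        z3 = _axis_vectors(par3, rho3, d23, e1, nu1, mu1)
        z4 = _axis_vectors(par4, rho4, 0.0, e2, nu2, mu2)
        z5 = _axis_vectors(par5, rho5, d45, e2, nu2, mu2)
        c1, s1 = np.cos(tau1), np.sin(tau1)
        c2, s2 = np.cos(tau2), np.sin(tau2)
        return (
            z2[0] + c1 * z2[1] + s1 * z2[2],
            z3[0] + c1 * z3[1] + s1 * z3[2],
            z4[0] + c2 * z4[1] + s2 * z4[2],
            z5[0] + c2 * z5[1] + s2 * z5[2],
        )

    # -- constraint coefficients --------------------------------------

    def _fit_matrices(self) -> None:
        """All three constraint coefficient matrices.

        F1/F3 sigma-dependence is exactly trig-linear, so three samples
        fit it; F2 is sigma-invariant (both axes rotate with the
        triangle) and is evaluated in the sigma = 0 realization.
        """
        red = self.red
        par2, rho2, par3, rho3, d23 = red.u1_cyl
        par4, rho4, par5, rho5, d45 = red.u2_cyl
        sigmas = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)
        f1_rows, f3_rows = [], []
        for s in sigmas:
            _, (e1, nu1, mu1), (e2, nu2, mu2) = self.triangle(s)
            v0, v1, v2 = _axis_vectors(par2, rho2, 0.0, e1, nu1, mu1)
            f1_rows.append([red.z1 @ v0 - red.c1, red.z1 @ v1, red.z1 @ v2])
            w0, w1, w2 = _axis_vectors(par5, rho5, d45, e2, nu2, mu2)
            f3_rows.append([self.z6 @ w0 - red.c3, self.z6 @ w1, self.z6 @ w2])
            if s == 0.0:
                a = _axis_vectors(par3, rho3, d23, e1, nu1, mu1)
                b = _axis_vectors(par4, rho4, 0.0, e2, nu2, mu2)
                m2 = np.array([[ai @ bj for bj in b] for ai in a])
                m2[0, 0] -= red.c2
        basis = np.stack(
            [np.ones(3), np.cos(sigmas), np.sin(sigmas)], axis=1
        )
        binv = np.linalg.inv(basis)
        self.m1 = binv @ np.asarray(f1_rows)
        self.m3 = binv @ np.asarray(f3_rows)
        self.m2 = m2


def _trig_to_quad(coeffs: np.ndarray) -> np.ndarray:
    """(A, B, C) -> ascending u-quadratic (A+B, 2C, A-B)."""
    a, b, c = coeffs
    return np.array([a + b, 2.0 * c, a - b])


def _h_samples(setup: _WorldSetup) -> np.ndarray:
    """The eliminant h(sigma) at the FFT sample points."""
    sigmas = 2.0 * np.pi * np.arange(_N_SIGMA) / _N_SIGMA
    basis = np.stack([np.ones(_N_SIGMA), np.cos(sigmas), np.sin(sigmas)], axis=1)
    q1 = basis @ setup.m1  # (N, 3) trig coeffs of F1 in tau1
    q3 = basis @ setup.m3
    q1 = np.stack([q1[:, 0] + q1[:, 1], 2.0 * q1[:, 2], q1[:, 0] - q1[:, 1]], axis=1)
    q3 = np.stack([q3[:, 0] + q3[:, 1], 2.0 * q3[:, 2], q3[:, 0] - q3[:, 1]], axis=1)

    # F2 as biquadratic in (u1, u2): P2[p, q] u1^p u2^q
    p2 = _TRIG_TO_POLY.T @ setup.m2 @ _TRIG_TO_POLY
    # coefficients of F2 in u1 at each of the 5 Chebyshev u2 nodes
    u2pow = np.vander(_U2_NODES, 3, increasing=True)  # (5, 3)
    f2_at_nodes = u2pow @ p2.T  # (5 nodes, 3 u1-coeffs ascending)

    # resultant in u1: 4x4 Sylvester of two quadratics, batched over
    # (sigma sample, u2 node)
    n = _N_SIGMA
    syl4 = np.zeros((n, 5, 4, 4))
    a = q1[:, ::-1]  # descending
    syl4[:, :, 0, 0:3] = a[:, None, :]
    syl4[:, :, 1, 1:4] = a[:, None, :]
    b = f2_at_nodes[:, ::-1]
    syl4[:, :, 2, 0:3] = b[None, :, :]
    syl4[:, :, 3, 1:4] = b[None, :, :]
    det4 = np.linalg.det(syl4)  # (n, 5)
    r12 = det4 @ _VAND_INV.T  # (n, 5) ascending u2-quartic coefficients

    # resultant in u2: 6x6 Sylvester of the quartic r12 and quadratic q3
    syl6 = np.zeros((n, 6, 6))
    ra = r12[:, ::-1]
    syl6[:, 0, 0:5] = ra
    syl6[:, 1, 1:6] = ra
    rb = q3[:, ::-1]
    for row in range(4):
        syl6[:, 2 + row, row : row + 3] = rb[:, None, :].reshape(n, 1, 3)[:, 0, :]
    return np.linalg.det(syl6)


def _sigma_roots(h: np.ndarray) -> np.ndarray:
    """Real sigma roots of the degree-8 trig polynomial h."""
    c = np.fft.fft(h) / _N_SIGMA
    # z-polynomial sum_{m=-8..8} c_m z^(m+8), z = exp(i sigma)
    coeffs = np.empty(17, dtype=complex)
    for m in range(-8, 9):
        coeffs[m + 8] = c[m % _N_SIGMA]
    scale = np.max(np.abs(coeffs))
    if scale == 0.0:
        raise IKNumericalError("identically vanishing eliminant (degenerate geometry)")
    coeffs = coeffs / scale
    # descending order for np.roots
    roots = np.roots(coeffs[::-1])
    if len(roots) == 0:
        return np.array([])
    on_circle = np.abs(np.log(np.abs(roots))) < 1e-4
    return np.angle(roots[on_circle])


def _trig_solve(coeffs: np.ndarray, tol: float = 1e-9) -> list[float]:
    """Roots of A + B cos(t) + C sin(t) = 0 in (-pi, pi]."""
    a, b, c = coeffs
    r = np.hypot(b, c)
    if r < tol:
        return []
    x = -a / r
    if abs(x) > 1.0 + 1e-9:
        return []
    x = float(np.clip(x, -1.0, 1.0))
    phase = float(np.arctan2(c, b))
    delta = float(np.arccos(x))
    return [wrap_angle(phase + delta), wrap_angle(phase - delta)]


def _reconstruct_thetas(setup: _WorldSetup, sigma, tau1, tau2, problem: IKProblem):
    """Sequential extraction of the six joint angles from axis directions."""
    z_dirs = setup.axis_z(sigma, tau1, tau2)  # z2..z5 world
    z_world = list(z_dirs) + [setup.z6]
    alphas = setup.red.alphas
    thetas = np.zeros(6)
    rot = np.eye(3)
    for i in range(5):
        rot = rot @ _rx(alphas[i])
        w = rot.T @ z_world[i]
        alpha_next = problem.links[i + 1].alpha_prev
        s = np.sin(alpha_next)
        if abs(s) < 1e-9:
            raise IKNumericalError("parallel consecutive axes in reconstruction")
        sign = 1.0 if s > 0 else -1.0
        thetas[i] = np.arctan2(sign * w[0], -sign * w[1])
        rot = rot @ _rz(thetas[i])
    rot = rot @ _rx(alphas[5])
    m = rot.T @ setup.end_rot
    thetas[5] = np.arctan2(m[1, 0], m[0, 0])
    return thetas


try:  # optional JIT of the Gauss-Newton kernel (hot path of sampling)
    from numba import njit as _njit

    @_njit(cache=True)
    def _gn_kernel(thetas, alphas, a_prev, d_off, t_close, target, iterations):
        ca = np.cos(alphas)
        sa = np.sin(alphas)
        prev_norm = 1e300
        for _ in range(iterations):
            ct = np.cos(thetas)
            st = np.sin(thetas)
            mats = np.zeros((6, 4, 4))
            for i in range(6):
                mats[i, 0, 0] = ct[i]
                mats[i, 0, 1] = -st[i]
                mats[i, 0, 3] = a_prev[i]
                mats[i, 1, 0] = st[i] * ca[i]
                mats[i, 1, 1] = ct[i] * ca[i]
                mats[i, 1, 2] = -sa[i]
                mats[i, 1, 3] = -d_off[i] * sa[i]
                mats[i, 2, 0] = st[i] * sa[i]
                mats[i, 2, 1] = ct[i] * sa[i]
                mats[i, 2, 2] = ca[i]
                mats[i, 2, 3] = d_off[i] * ca[i]
                mats[i, 3, 3] = 1.0
            prefix = np.zeros((7, 4, 4))
            prefix[0] = np.eye(4)
            for i in range(6):
                prefix[i + 1] = prefix[i] @ mats[i]
            suffix = np.zeros((7, 4, 4))
            suffix[6] = t_close
            for i in range(5, -1, -1):
                suffix[i] = mats[i] @ suffix[i + 1]
            full = prefix[0] @ suffix[0]
            r = np.empty(12)
            for a in range(3):
                for b in range(4):
                    r[a * 4 + b] = full[a, b] - target[a, b]
            r_norm = np.sqrt(np.sum(r * r))
            if r_norm < 1e-13:
                break
            if r_norm > 0.95 * prev_norm and r_norm > 1e-10:
                break
            prev_norm = r_norm
            jac = np.empty((12, 6))
            dmat = np.zeros((4, 4))
            for i in range(6):
                dmat[0, 0] = -st[i]
                dmat[0, 1] = -ct[i]
                dmat[1, 0] = ct[i] * ca[i]
                dmat[1, 1] = -st[i] * ca[i]
                dmat[2, 0] = ct[i] * sa[i]
                dmat[2, 1] = -st[i] * sa[i]
                col = prefix[i] @ (dmat @ suffix[i + 1])
                for a in range(3):
                    for b in range(4):
                        jac[a * 4 + b, i] = col[a, b]
            jtj = jac.T @ jac + 1e-14 * np.eye(6)
            jtr = jac.T @ r
            step = np.linalg.solve(jtj, -jtr)
            thetas = thetas + step
            if np.sum(step * step) < 1e-30:
                break
        return thetas

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _polish(problem: IKProblem, thetas: np.ndarray, iterations: int = 8) -> np.ndarray:
    """Gauss-Newton refinement of the closure equations.

    Convergence is quadratic from a nearby start; a residual that stops
    shrinking signals an unreachable target, and the loop exits early.
    """
    if _HAVE_NUMBA:
        alphas = np.array([l.alpha_prev for l in problem.links])
        a_prev = np.array([l.a_prev for l in problem.links])
        d_off = np.array([l.d for l in problem.links])
        out = _gn_kernel(
            np.asarray(thetas, float),
            alphas,
            a_prev,
            d_off,
            np.asarray(problem.t_close, float),
            np.ascontiguousarray(problem.target[:3, :4]),
            iterations,
        )
        return wrap_angle(out)
    target = problem.target[:3, :4]
    alphas = np.array([l.alpha_prev for l in problem.links])
    a_prev = np.array([l.a_prev for l in problem.links])
    d_off = np.array([l.d for l in problem.links])
    ca, sa = np.cos(alphas), np.sin(alphas)
    prev_norm = np.inf
    for _ in range(iterations):
        ct, st = np.cos(thetas), np.sin(thetas)
        mats = np.zeros((6, 4, 4))
        mats[:, 0, 0] = ct
        mats[:, 0, 1] = -st
        mats[:, 0, 3] = a_prev
        mats[:, 1, 0] = st * ca
        mats[:, 1, 1] = ct * ca
        mats[:, 1, 2] = -sa
        mats[:, 1, 3] = -d_off * sa
        mats[:, 2, 0] = st * sa
        mats[:, 2, 1] = ct * sa
        mats[:, 2, 2] = ca
        mats[:, 2, 3] = d_off * ca
        mats[:, 3, 3] = 1.0
        prefix = [np.eye(4)]
        for i in range(6):
            prefix.append(prefix[i] @ mats[i])
        suffix = [None] * 7
        suffix[6] = problem.t_close
        for i in range(5, -1, -1):
            suffix[i] = mats[i] @ suffix[i + 1]
        r = ((prefix[0] @ suffix[0])[:3, :4] - target).ravel()
        r_norm = float(r @ r) ** 0.5
        if r_norm < 1e-13:
            break
        if r_norm > 0.95 * prev_norm and r_norm > 1e-10:
            # stagnating: no solution on this branch
            break
        prev_norm = r_norm
        dmats = np.zeros((6, 4, 4))
        dmats[:, 0, 0] = -st
        dmats[:, 0, 1] = -ct
        dmats[:, 1, 0] = ct * ca
        dmats[:, 1, 1] = -st * ca
        dmats[:, 2, 0] = ct * sa
        dmats[:, 2, 1] = -st * sa
        jac = np.empty((12, 6))
        for i in range(6):
            jac[:, i] = (prefix[i] @ dmats[i] @ suffix[i + 1])[:3, :4].ravel()
        jtj = jac.T @ jac
        jtr = jac.T @ r
        try:
            step = np.linalg.solve(jtj + 1e-14 * np.eye(6), -jtr)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        thetas = thetas + step
        if float(step @ step) < 1e-30:
            break
    return wrap_angle(thetas)


def solve(problem: IKProblem, reduction: "_Reduction | None" = None) -> IKSolutionSet:
    """All real solutions of the 6R loop-closure problem.

    Returns an empty set for unreachable targets.  Raises
    :class:`IKNumericalError` on degenerate geometry or conditioning
    failure — callers treating both outcomes as a Monte Carlo rejection
    should catch it explicitly.  ``reduction`` may carry the
    configuration-invariant geometry precomputed by a previous call on
    the same link constants (rigid geometry makes it reusable).
    """
    red = reduction if reduction is not None else _Reduction(problem)
    setup = _WorldSetup(red, problem)
    if not setup.feasible:
        return IKSolutionSet(np.empty((0, 6)), np.empty(0))

    h = _h_samples(setup)
    scale = np.max(np.abs(h))
    m_scale = max(np.max(np.abs(setup.m1)), np.max(np.abs(setup.m2)), np.max(np.abs(setup.m3)))
    if not np.isfinite(scale) or scale < 1e-10 * max(m_scale, 1.0) ** 6:
        raise IKNumericalError("ill-conditioned eliminant")

    basis = lambda t: np.array([1.0, np.cos(t), np.sin(t)])
    found: list[np.ndarray] = []
    residuals: list[float] = []
    for sigma in _sigma_roots(h):
        f1 = setup.m1.T @ basis(sigma)
        for tau1 in _trig_solve(f1):
            f2 = setup.m2.T @ basis(tau1)
            for tau2 in _trig_solve(f2):
                f3 = setup.m3.T @ basis(sigma)
                if abs(f3 @ basis(tau2)) > 1e-5 * max(1.0, np.max(np.abs(f3))):
                    continue
                try:
                    thetas = _reconstruct_thetas(setup, sigma, tau1, tau2, problem)
                except IKNumericalError:
                    continue
                thetas = _polish(problem, thetas)
                res = closure_residual(problem, thetas)
                if res >= _RESIDUAL_TOL:
                    continue
                if any(np.all(np.abs(wrap_angle(thetas - f)) < _MERGE_TOL) for f in found):
                    continue
                found.append(thetas)
                residuals.append(res)

    if not found:
        return IKSolutionSet(np.empty((0, 6)), np.empty(0))
    sols = np.asarray(found)
    res = np.asarray(residuals)
    order = np.argsort(sols[:, 0], kind="stable")
    return IKSolutionSet(sols[order], res[order])


def solve_continuation(problem: IKProblem, theta_start: np.ndarray):
    """Track the solution branch continuously connected to ``theta_start``.

    Gauss-Newton refinement of the closure equations from the previous
    conformation's angles.  For the small target perturbations of
    Monte Carlo moves this converges to the nearest solution — the one
    closest-selection would pick — in a few iterations; it returns
    None when no nearby branch exists (the move is then rejected, as
    any remaining solutions lie beyond the jump threshold).
    """
    thetas = _polish(problem, np.asarray(theta_start, float), iterations=25)
    if closure_residual(problem, thetas) >= _RESIDUAL_TOL:
        return None
    return thetas


def select_solution(
    solutions: IKSolutionSet,
    current: np.ndarray,
    strategy: str = "closest",
    threshold: float = np.inf,
    rng: np.random.Generator | None = None,
    energy_fn=None,
    kt: float = 1.0,
):
    """Pick one solution, or None to signal rejection.

    ``random`` draws uniformly; ``closest`` minimizes the Euclidean
    norm of wrapped angle differences to ``current`` and rejects when
    that distance exceeds ``threshold`` (minimizing conformational
    jumps); ``boltzmann_weighted`` draws with probability proportional
    to ``exp(-E/kT)`` of each candidate, using ``energy_fn(thetas)``.
    """
    if solutions.count == 0:
        return None
    if strategy == "random":
        if rng is None:
            raise ValueError("random strategy needs an rng")
        return solutions.solutions[rng.integers(solutions.count)]
    if strategy == "closest":
        diffs = wrap_angle(solutions.solutions - np.asarray(current))
        dists = np.linalg.norm(diffs, axis=1)
        best = int(np.argmin(dists))
        if dists[best] > threshold:
            return None
        return solutions.solutions[best]
    if strategy == "boltzmann_weighted":
        if energy_fn is None or rng is None:
            raise ValueError("boltzmann_weighted strategy needs energy_fn and rng")
        energies = np.array([energy_fn(s) for s in solutions.solutions])
        w = np.exp(-(energies - energies.min()) / kt)
        w /= w.sum()
        return solutions.solutions[rng.choice(solutions.count, p=w)]
    raise ValueError(f"unknown selection strategy {strategy!r}")
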