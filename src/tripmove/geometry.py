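"""Rigid-transform and internal-coordinate geometry primitives.

All coordinates are in Angstrom and all angles in radians.  Rigid
transforms are plain 4x4 numpy arrays ``[[R, t], [0, 1]]`` with an
orthonormal, right-handed rotation block.  Dihedral angles follow the
IUPAC sign convention: looking from the second to the third atom, the
far bond rotates clockwise for positive angles, and the cis (eclipsed)
arrangement is 0.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RigidTransform",
    "identity",
    "make_transform",
    "transform_inverse",
    "transform_points",
    "is_rigid_transform",
    "require_rigid_transform",
    "rotation_about_axis",
    "wrap_angle",
    "angle_between",
    "bond_angle",
    "dihedral",
    "place_atom",
    "frame_from_points",
    "line_intersection",
    "random_rotation",
    "superpose",
]

# A rigid transform is any (4, 4) float array satisfying is_rigid_transform.
RigidTransform = np.ndarray


def identity() -> RigidTransform:
    return np.eye(4)


def make_transform(rotation: np.ndarray, translation: np.ndarray) -> RigidTransform:
    t = np.eye(4)
    t[:3, :3] = rotation
    t[:3, 3] = translation
    return t


def transform_inverse(t: RigidTransform) -> RigidTransform:
    r = t[:3, :3]
    out = np.eye(4)
    out[:3, :3] = r.T
    out[:3, 3] = -r.T @ t[:3, 3]
    return out


def transform_points(t: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Apply ``t`` to an (n, 3) array (or a single point)."""
    return points @ t[:3, :3].T + t[:3, 3]


def is_rigid_transform(t: np.ndarray, tol: float = 1e-9) -> bool:
    if t.shape != (4, 4):
        return False
    if not np.array_equal(t[3], [0.0, 0.0, 0.0, 1.0]):
        return False
    r = t[:3, :3]
    if not np.allclose(r.T @ r, np.eye(3), atol=tol):
        return False
    return np.linalg.det(r) > 0.0


def require_rigid_transform(t: np.ndarray, tol: float = 1e-9) -> None:
    if not is_rigid_transform(t, tol):
        raise ValueError("not a valid rigid transform (orthonormality/bottom-row check failed)")


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis, Rodrigues form."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("zero rotation axis")
    x, y, z = axis / n
    c, s = np.cos(angle), np.sin(angle)
    cc = 1.0 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )


def wrap_angle(angle):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Numerically stable unsigned angle between two vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-length vector in angle computation")
    # atan2 form avoids precision loss near 0 and pi
    cross = np.linalg.norm(np.cross(u, v))
    dot = float(u @ v)
    return float(np.arctan2(cross, dot))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b."""
    return angle_between(a - b, c - b)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle of the bond p1-p2 (IUPAC convention, cis = 0)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m @ n2)
    return float(np.arctan2(y, x))


def place_atom(
    ref1: np.ndarray,
    ref2: np.ndarray,
    ref3: np.ndarray,
    length: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Natural-extension (NeRF) placement of an atom bonded to ``ref3``.

    The new atom D satisfies |D - ref3| = length, the angle
    ref2-ref3-D equals ``angle`` and the dihedral ref1-ref2-ref3-D
    equals ``torsion``.  (Scalar arithmetic: this sits in the inner
    rebuild loop of every Monte Carlo move.)
    """
    import math

    ax, ay, az = ref1.tolist() if hasattr(ref1, "tolist") else ref1
    bx, by, bz = ref2.tolist() if hasattr(ref2, "tolist") else ref2
    cx, cy, cz = ref3.tolist() if hasattr(ref3, "tolist") else ref3
    ux, uy, uz = cx - bx, cy - by, cz - bz
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx, vy, vz = bx - ax, by - ay, bz - az
    nx = vy * uz - vz * uy
    ny = vz * ux - vx * uz
    nz = vx * uy - vy * ux
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms in NeRF placement")
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * uz - nz * uy
    my = nz * ux - nx * uz
    mz = nx * uy - ny * ux
    d0 = -length * math.cos(angle)
    sl = length * math.sin(angle)
    d1 = sl * math.cos(torsion)
    d2 = -sl * math.sin(torsion)
    return np.array(
        [
            cx + d0 * ux + d1 * mx + d2 * nx,
            cy + d0 * uy + d1 * my + d2 * ny,
            cz + d0 * uz + d1 * mz + d2 * nz,
        ]
    )


def frame_from_points(origin: np.ndarray, z_toward: np.ndarray, plane_ref: np.ndarray) -> RigidTransform:
    """Deterministic orthonormal frame from three points.

    z points from ``origin`` toward ``z_toward``; x is the component of
    (plane_ref - origin) perpendicular to z; y completes a right-handed
    set.  Used for particle frames, so the same three atoms always give
    the same frame.
    """
    import math

    ox, oy, oz = origin.tolist() if hasattr(origin, "tolist") else origin
    zx, zy, zz = z_toward.tolist() if hasattr(z_toward, "tolist") else z_toward
    px, py, pz = plane_ref.tolist() if hasattr(plane_ref, "tolist") else plane_ref
    zx, zy, zz = zx - ox, zy - oy, zz - oz
    nz = math.sqrt(zx * zx + zy * zy + zz * zz)
    if nz < 1e-12:
        raise ValueError("degenerate frame: origin and z reference coincide")
    zx, zy, zz = zx / nz, zy / nz, zz / nz
    xx, xy, xz = px - ox, py - oy, pz - oz
    dot = xx * zx + xy * zy + xz * zz
    xx, xy, xz = xx - dot * zx, xy - dot * zy, xz - dot * zz
    nx = math.sqrt(xx * xx + xy * xy + xz * xz)
    if nx < 1e-9:
        raise ValueError("degenerate frame: plane reference collinear with z axis")
    xx, xy, xz = xx / nx, xy / nx, xz / nx
    yx = zy * xz - zz * xy
    yy = zz * xx - zx * xz
    yz = zx * xy - zy * xx
    return np.array(
        [
            [xx, yx, zx, ox],
            [xy, yy, zy, oy],
            [xz, yz, zz, oz],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def line_intersection(p1, d1, p2, d2, tol: float = 1e-6):
    """Intersection point of two nearly concurrent lines.

    Returns the midpoint of the closest-approach segment.  Raises if the
    lines are parallel or the gap exceeds ``tol``.
    """
    d1 = np.asarray(d1, float) / np.linalg.norm(d1)
    d2 = np.asarray(d2, float) / np.linalg.norm(d2)
    w = np.asarray(p1, float) - np.asarray(p2, float)
    a = 1.0
    b = float(d1 @ d2)
    denom = a - b * b
    if denom < 1e-12:
        raise ValueError("parallel axes: no well-defined intersection")
    d = float(d1 @ w)
    e = float(d2 @ w)
    t1 = (b * e - d) / denom
    t2 = (e - b * d) / denom
    q1 = p1 + t1 * d1
    q2 = p2 + t2 * d2
    if np.linalg.norm(q1 - q2) > tol:
        raise ValueError("skew axes: lines do not intersect within tolerance")
    return 0.5 * (q1 + q2)


def random_rotation(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    """Rotation by U(-max_angle, max_angle) about a uniform random axis."""
    v = rng.normal(size=3)
    while np.linalg.norm(v) < 1e-12:  # pragma: no cover
        v = rng.normal(size=3)
    return rotation_about_axis(v, rng.uniform(-max_angle, max_angle))


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares (Kabsch) superposition of two (n, 3) point sets.

    Returns the transformed mobile coordinates and the rigid transform.
    """
    from scipy.spatial.transform import Rotation

    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    r = rot.as_matrix()
    t = ref_c - r @ mob_c
    return mobile @ r.T + t, make_transform(r, t)
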