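"""Modified Denavit-Hartenberg (mDH) chain kinematics.

A serial kinematic chain is a sequence of :class:`MDHLink` records.  In
the mDH convention (Craig variant) the transform from frame ``i-1`` to
frame ``i`` is ``Rx(alpha_prev) . Tx(a_prev) . Rz(theta) . Tz(d)``:
frame ``i`` has its z-axis along joint axis ``i`` and its x-axis along
the common normal to the next joint axis.  ``theta`` is the variable
bond torsion for revolute joints; rigid peptide bonds appear as links
with ``variable=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import RigidTransform, transform_inverse

__all__ = ["MDHLink", "mdh_transform", "forward_kinematics", "links_from_axes"]


@dataclass(frozen=True)
class MDHLink:
    """One joint of an mDH chain.

    ``a_prev`` (link offset, A) and ``alpha_prev`` (link twist, rad)
    describe the constant relation between the previous joint axis and
    this one; ``d`` (A) is the constant offset along this axis and
    ``theta`` (rad) the bond torsion, the only parameter that changes
    during sampling when ``variable`` is True.
    """

    a_prev: float
    alpha_prev: float
    d: float
    theta: float
    variable: bool = True

    def with_theta(self, theta: float) -> "MDHLink":
        return replace(self, theta=theta)


def mdh_transform(link: MDHLink) -> RigidTransform:
    """Homogeneous transform of one mDH link."""
    ct, st = np.cos(link.theta), np.sin(link.theta)
    ca, sa = np.cos(link.alpha_prev), np.sin(link.alpha_prev)
    d, a = link.d, link.a_prev
    return np.array(
        [
            [ct, -st, 0.0, a],
            [st * ca, ct * ca, -sa, -d * sa],
            [st * sa, ct * sa, ca, d * ca],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def forward_kinematics(links, base: RigidTransform | None = None) -> list[RigidTransform]:
    """Cumulative frames of an mDH chain.

    Returns ``len(links) + 1`` transforms: the base frame followed by
    the frame of each successive link, so the last entry equals
    ``base @ T1 @ ... @ Tn``.
    """
    frame = np.eye(4) if base is None else np.asarray(base, dtype=float)
    frames = [frame]
    for link in links:
        frame = frame @ mdh_transform(link)
        frames.append(frame)
    return frames


def _foot_parameters(p1, z1, p2, z2):
    """Closest-approach parameters t1, t2 for two lines p + t z."""
    b = float(z1 @ z2)
    denom = 1.0 - b * b
    if denom < 1e-14:
        raise ValueError("parallel consecutive joint axes: mDH frame unparameterizable")
    w = p1 - p2
    d = float(z1 @ w)
    e = float(z2 @ w)
    return (b * e - d) / denom, (e - b * d) / denom


def links_from_axes(
    base: RigidTransform,
    axes: list[tuple[np.ndarray, np.ndarray]],
    end_frame: RigidTransform,
    variable: list[bool] | None = None,
    tol: float = 1e-8,
):
    """Derive mDH parameters for a chain of revolute joint axes.

    ``axes`` is a list of ``(point, direction)`` pairs giving each joint
    axis in world coordinates at the current (reference) conformation.
    The base frame's z-axis must be collinear (same direction) with the
    first joint axis, which holds for particle frames by construction.

    Returns ``(links, t_close)`` where ``links[i].theta`` is the joint
    value at the reference conformation and ``t_close`` is the constant
    transform from the last mDH frame to ``end_frame``, so that
    ``base . T1 ... Tn . t_close == end_frame`` at the reference.

    Raises ``ValueError`` for degenerate geometry (parallel or collinear
    consecutive axes).
    """
    base = np.asarray(base, dtype=float)
    n = len(axes)
    if variable is None:
        variable = [True] * n
    dirs = [np.asarray(d, float) / np.linalg.norm(d) for _, d in axes]
    pts = [np.asarray(p, float) for p, _ in axes]

    if abs(float(base[:3, 2] @ dirs[0]) - 1.0) > 1e-9:
        raise ValueError("base frame z-axis must lie along the first joint axis")

    # Build the mDH frame on each axis: origin at the foot of the common
    # normal to the next axis, x along that normal.
    frames = [base]
    for i in range(n):
        z = dirs[i]
        if i < n - 1:
            t1, _ = _foot_parameters(pts[i], z, pts[i + 1], dirs[i + 1])
            origin = pts[i] + t1 * z
            x = np.cross(z, dirs[i + 1])
            x /= np.linalg.norm(x)
        else:
            # Last axis: no successor; anchor deterministically near the
            # end frame and borrow a perpendicular reference from it.
            origin = pts[i] + float(z @ (end_frame[:3, 3] - pts[i])) * z
            x = end_frame[:3, 0] - float(end_frame[:3, 0] @ z) * z
            if np.linalg.norm(x) < 1e-9:
                x = end_frame[:3, 1] - float(end_frame[:3, 1] @ z) * z
            x /= np.linalg.norm(x)
        f = np.eye(4)
        f[:3, 0] = x
        f[:3, 2] = z
        f[:3, 1] = np.cross(z, x)
        f[:3, 3] = origin
        frames.append(f)

    links = []
    for i in range(n):
        rel = transform_inverse(frames[i]) @ frames[i + 1]
        alpha = float(np.arctan2(-rel[1, 2], rel[2, 2]))
        theta = float(np.arctan2(-rel[0, 1], rel[0, 0]))
        a = float(rel[0, 3])
        ca, sa = np.cos(alpha), np.sin(alpha)
        d = float(rel[2, 3] * ca - rel[1, 3] * sa)
        link = MDHLink(a_prev=a, alpha_prev=alpha, d=d, theta=theta, variable=variable[i])
        if not np.allclose(mdh_transform(link), rel, atol=tol):
            raise ValueError(f"axis geometry at joint {i} does not admit mDH parameters")
        links.append(link)

    t_close = transform_inverse(frames[-1]) @ np.asarray(end_frame, dtype=float)
    return links, t_close
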