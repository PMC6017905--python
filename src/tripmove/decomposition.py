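"""Segmentation of a backbone chain into tripeptides and particles.

A tripeptide is a fragment of three consecutive residues whose backbone
carries six variable torsions (three phi/psi pairs) — the shortest
fragment with full 6-DOF mobility of its end frame relative to its
base frame.  The oriented reference frame attached to the first rigid
body of each tripeptide backbone is its *particle*: the whole backbone
conformation is recoverable from the particle poses plus the torsions
of the tripeptides and of the two terminal leftover fragments.

The choice of the first segmented residue (``start_offset``) is
arbitrary and always explicit; no global segmentation state exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import BackboneChain
from .geometry import RigidTransform, frame_from_points, place_atom, wrap_angle

__all__ = ["Tripeptide", "TripeptideDecomposition", "decompose", "particle_poses",
           "reconstruct_backbone", "assign_mdh_parameters", "StaleChainError"]


class StaleChainError(RuntimeError):
    """The chain has pending torsion edits; call ``refresh()`` first."""


@dataclass(frozen=True)
class Tripeptide:
    index: int
    residues: tuple[int, int, int]

    @property
    def first(self) -> int:
        return self.residues[0]

    @property
    def last(self) -> int:
        return self.residues[2]

    @property
    def torsion_keys(self):
        """The six variable torsions, base to end."""
        keys = []
        for r in self.residues:
            keys.append(("phi", r))
            keys.append(("psi", r))
        return keys


@dataclass(frozen=True)
class TripeptideDecomposition:
    start_offset: int
    tripeptides: tuple[Tripeptide, ...]
    n_term_fragment: tuple[int, ...]
    c_term_fragment: tuple[int, ...]
    n_residues: int

    @property
    def n_tripeptides(self) -> int:
        return len(self.tripeptides)

    def tripeptide_of_residue(self, res: int) -> Tripeptide | None:
        k = (res - self.start_offset) // 3
        if res < self.start_offset or k >= len(self.tripeptides):
            return None
        return self.tripeptides[k]


def decompose(chain: BackboneChain, start_offset: int = 0) -> TripeptideDecomposition:
    """Tile the chain with tripeptides starting at ``start_offset``.

    Residues before the offset form the N-terminal fragment; the
    ``(n - start_offset) mod 3`` leftover residues form the C-terminal
    fragment.  Raises ``ValueError`` when no complete tripeptide fits.
    """
    if start_offset not in (0, 1, 2):
        raise ValueError("start_offset must be 0, 1 or 2")
    n = chain.n_residues
    n_trip = (n - start_offset) // 3
    if n_trip < 1:
        raise ValueError(f"chain of {n} residues too short for a tripeptide at offset {start_offset}")
    trips = tuple(
        Tripeptide(k, (start_offset + 3 * k, start_offset + 3 * k + 1, start_offset + 3 * k + 2))
        for k in range(n_trip)
    )
    return TripeptideDecomposition(
        start_offset=start_offset,
        tripeptides=trips,
        n_term_fragment=tuple(range(start_offset)),
        c_term_fragment=tuple(range(start_offset + 3 * n_trip, n)),
        n_residues=n,
    )


def junction_frame(chain: BackboneChain, res: int) -> RigidTransform:
    """Oriented frame of the rigid peptide unit entering residue ``res``.

    Origin at N of ``res``, z toward its CA, x referenced on the
    preceding carbonyl carbon (virtual at the chain start).  ``res`` may
    equal ``n_residues``, giving the frame on the virtual end anchors.
    """
    if chain.dirty:
        raise StaleChainError("chain edited without refresh; particle poses would be stale")
    n_at = chain._atom_or_virtual(res, "N")
    ca_at = chain._atom_or_virtual(res, "CA")
    c_prev = chain._atom_or_virtual(res - 1, "C")
    return frame_from_points(n_at, ca_at, c_prev)


def particle_pose(chain: BackboneChain, decomp: TripeptideDecomposition, k: int) -> RigidTransform:
    """Pose of the particle (base frame) of tripeptide ``k``."""
    return junction_frame(chain, decomp.tripeptides[k].first)


def end_frame(chain: BackboneChain, decomp: TripeptideDecomposition, k: int) -> RigidTransform:
    """End frame of tripeptide ``k`` (= particle of tripeptide ``k+1``
    when one follows)."""
    return junction_frame(chain, decomp.tripeptides[k].last + 1)


def particle_poses(chain: BackboneChain, decomp: TripeptideDecomposition) -> list[RigidTransform]:
    """One oriented-particle pose per tripeptide."""
    return [particle_pose(chain, decomp, k) for k in range(decomp.n_tripeptides)]


def assign_mdh_parameters(chain: BackboneChain):
    """Derive the mDH link chain of the whole backbone.

    Joints alternate phi, psi (variable) and omega (fixed — the rigid
    peptide bond appears as a constant link that the frame construction
    absorbs).  Returns ``(links, base_frame, t_close)`` such that
    forward kinematics from ``base_frame`` through the links and
    ``t_close`` reproduces the chain-end junction frame, and each link
    frame's origin coincides with the backbone atom its joint axis
    pair intersects at.

    Raises ``ValueError`` for degenerate geometry (collinear
    consecutive bonds give parallel joint axes with no common normal).
    """
    from .mdh import links_from_axes

    chain.refresh()
    base = junction_frame(chain, 0)
    end = junction_frame(chain, chain.n_residues)
    axes = []
    variable = []
    for i in range(chain.n_residues):
        n_at = chain.coords[chain.atom_index(i, "N")]
        ca = chain.coords[chain.atom_index(i, "CA")]
        c = chain.coords[chain.atom_index(i, "C")]
        n_next = chain._atom_or_virtual(i + 1, "N")
        axes.append((n_at, ca - n_at))
        axes.append((ca, c - ca))
        axes.append((c, n_next - c))
        variable.extend((True, True, False))
    links, t_close = links_from_axes(base, axes, end, variable)
    return links, base, t_close


def reconstruct_backbone(
    chain: BackboneChain,
    decomp: TripeptideDecomposition,
    poses: list[RigidTransform] | None = None,
) -> dict[tuple[int, str], np.ndarray]:
    """Rebuild every backbone N/CA/C position from particle poses and
    torsions alone (the particle-representation completeness check).

    Uses the chain only for its rigid geometry and torsion values, not
    its Cartesian coordinates.  Returns a map ``(res, atom) -> xyz``.
    """
    if poses is None:
        poses = particle_poses(chain, decomp)
    out: dict[tuple[int, str], np.ndarray] = {}

    def anchor_from_frame(frame: np.ndarray, res: int):
        """N, CA and reconstructed previous-C from a junction frame."""
        geom = chain.residues[res] if res < chain.n_residues else chain.residues[-1]
        bond_cn = chain.residues[res - 1].bond_c_n if res > 0 else geom.bond_c_n
        origin = frame[:3, 3]
        z = frame[:3, 2]
        x = frame[:3, 0]
        n_at = origin
        ca_at = origin + geom.bond_n_ca * z
        a = geom.angle_c_n_ca
        c_prev = origin + bond_cn * (np.cos(a) * z + np.sin(a) * x)
        return c_prev, n_at, ca_at

    # forward pass: each tripeptide from its own particle
    for trip in decomp.tripeptides:
        frame = poses[trip.index]
        c_prev, n_at, ca_at = anchor_from_frame(frame, trip.first)
        for r in trip.residues:
            geom = chain.residues[r]
            out[(r, "N")] = n_at
            out[(r, "CA")] = ca_at
            c_at = place_atom(c_prev, n_at, ca_at, geom.bond_ca_c, geom.angle_n_ca_c, chain.phi[r])
            out[(r, "C")] = c_at
            n_new = place_atom(n_at, ca_at, c_at, geom.bond_c_n, geom.angle_ca_c_n, chain.psi[r])
            if r + 1 <= chain.n_residues - 1:
                g2 = chain.residues[r + 1]
            else:
                g2 = geom
            ca_new = place_atom(ca_at, c_at, n_new, g2.bond_n_ca, g2.angle_c_n_ca, chain.omega[r])
            c_prev, n_at, ca_at = c_at, n_new, ca_new

    # C-terminal fragment: continue forward from the last tripeptide
    for r in decomp.c_term_fragment:
        geom = chain.residues[r]
        out[(r, "N")] = n_at
        out[(r, "CA")] = ca_at
        c_at = place_atom(c_prev, n_at, ca_at, geom.bond_ca_c, geom.angle_n_ca_c, chain.phi[r])
        out[(r, "C")] = c_at
        n_new = place_atom(n_at, ca_at, c_at, geom.bond_c_n, geom.angle_ca_c_n, chain.psi[r])
        g2 = chain.residues[r + 1] if r + 1 < chain.n_residues else geom
        ca_new = place_atom(ca_at, c_at, n_new, g2.bond_n_ca, g2.angle_c_n_ca, chain.omega[r])
        c_prev, n_at, ca_at = c_at, n_new, ca_new

    # N-terminal fragment: walk backward from the first particle.
    # State: (C of residue r, N and CA of residue r+1), known exactly
    # from the junction frame at the segmentation start.
    if decomp.n_term_fragment:
        first = decomp.tripeptides[0].first
        c_r, n_next, ca_next = anchor_from_frame(poses[0], first)
        phi, psi, omega = chain.phi, chain.psi, chain.omega
        for r in reversed(decomp.n_term_fragment):
            geom = chain.residues[r]
            out[(r, "C")] = c_r
            ca_r = place_atom(ca_next, n_next, c_r, geom.bond_ca_c, geom.angle_ca_c_n, omega[r])
            n_r = place_atom(n_next, c_r, ca_r, geom.bond_n_ca, geom.angle_n_ca_c, psi[r])
            out[(r, "CA")] = ca_r
            out[(r, "N")] = n_r
            if r > 0:
                g_prev = chain.residues[r - 1]
                c_r = place_atom(c_r, ca_r, n_r, g_prev.bond_c_n, geom.angle_c_n_ca, phi[r])
                n_next, ca_next = n_r, ca_r
    return out
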