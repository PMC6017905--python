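"""Full-atom polypeptide chain under the rigid-geometry assumption.

A :class:`BackboneChain` keeps internal coordinates (phi, psi, fixed
omega, side-chain chi) and Cartesian coordinates mutually consistent.
Bond lengths and bond angles are constants taken from a
:class:`~tripmove.residues.GeometryTable` (or measured once from input
coordinates) and never change; the torsions are the only degrees of
freedom.

Two virtual anchor atoms extend each chain end (a carbonyl carbon
before the first residue, an amide N/CA pair after the last) so that
every residue has a defined (phi, psi) pair.  Terminal torsions whose
reference atoms are virtual are flagged, not dropped.

Rebuild semantics: editing a torsion through the public setters marks
the chain dirty from that residue; ``refresh()`` then re-derives all
downstream Cartesian coordinates (pivot semantics).  Fixed-end moves
instead use ``apply_torsion_updates`` with an explicit residue span,
which rebuilds only the atoms inside the span and leaves everything
downstream bit-identical (the inverse-kinematics closure guarantees
consistency at the far junction).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .geometry import bond_angle, dihedral, place_atom, wrap_angle
from .residues import GeometryTable, ResidueGeometry, SideChainAtom

__all__ = ["BackboneChain", "build_chain_from_internal"]


class BackboneChain:
    def __init__(
        self,
        residues: list[ResidueGeometry],
        phi: np.ndarray,
        psi: np.ndarray,
        omega: np.ndarray,
        chi: list[np.ndarray],
    ):
        n = len(residues)
        if not (len(phi) == len(psi) == len(omega) == len(chi) == n):
            raise ValueError("torsion arrays must have one entry per residue")
        for i, (geom, c) in enumerate(zip(residues, chi)):
            if len(c) != geom.n_chi:
                raise ValueError(
                    f"residue {i} ({geom.name}): expected {geom.n_chi} chi torsions, got {len(c)}"
                )
        self.residues = list(residues)
        self._phi = wrap_angle(np.asarray(phi, float)) + np.zeros(n)
        self._psi = wrap_angle(np.asarray(psi, float)) + np.zeros(n)
        self._omega = wrap_angle(np.asarray(omega, float)) + np.zeros(n)
        self._chi = [np.atleast_1d(wrap_angle(np.asarray(c, float))) for c in chi]

        # flat atom table
        self.atom_names: list[str] = []
        self.atom_res: list[int] = []
        self._index: dict[tuple[int, str], int] = {}
        for i, geom in enumerate(residues):
            for name in geom.atom_names:
                self._index[(i, name)] = len(self.atom_names)
                self.atom_names.append(name)
                self.atom_res.append(i)
        self.atom_res = np.asarray(self.atom_res)
        self.atom_elements = np.asarray([n[0] for n in self.atom_names])
        self.coords = np.zeros((len(self.atom_names), 3))

        # virtual anchors: C before residue 0, N/CA after the last residue
        self._c_prev = np.zeros(3)
        self._n_next = np.zeros(3)
        self._ca_next = np.zeros(3)

        self._dirty_from: int | None = 0
        self.version = 0
        self.metadata: dict = {}
        self._seed_initial()
        self.refresh()

    # -- basic queries -------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def sequence(self) -> list[str]:
        return [g.name for g in self.residues]

    def atom_index(self, res: int, name: str) -> int:
        return self._index[(res, name)]

    def has_atom(self, res: int, name: str) -> bool:
        return (res, name) in self._index

    def coord(self, res: int, name: str) -> np.ndarray:
        self.refresh()
        return self.coords[self._index[(res, name)]]

    @property
    def phi(self) -> np.ndarray:
        return self._phi.copy()

    @property
    def psi(self) -> np.ndarray:
        return self._psi.copy()

    @property
    def omega(self) -> np.ndarray:
        return self._omega.copy()

    def chi(self, res: int) -> np.ndarray:
        return self._chi[res].copy()

    @property
    def terminal_torsion_flags(self) -> dict[str, bool]:
        """Torsions defined only through virtual anchor atoms."""
        return {"phi_first_virtual": True, "psi_last_virtual": True, "omega_last_virtual": True}

    def torsion_vector(self) -> np.ndarray:
        """Backbone torsions as [phi0, psi0, phi1, psi1, ...]."""
        out = np.empty(2 * self.n_residues)
        out[0::2] = self._phi
        out[1::2] = self._psi
        return out

    def ca_coords(self) -> np.ndarray:
        self.refresh()
        return self.coords[[self._index[(i, "CA")] for i in range(self.n_residues)]]

    def backbone_indices(self) -> np.ndarray:
        return np.asarray(
            [i for i, name in enumerate(self.atom_names) if name in ("N", "CA", "C", "O")]
        )

    def bonded_pairs(self) -> list[tuple[int, int]]:
        """Covalent bonds between modeled (non-virtual) atoms."""
        pairs = []
        for i, geom in enumerate(self.residues):
            idx = lambda name: self._index[(i, name)]
            pairs.append((idx("N"), idx("CA")))
            pairs.append((idx("CA"), idx("C")))
            pairs.append((idx("C"), idx("O")))
            if geom.has_cb:
                pairs.append((idx("CA"), idx("CB")))
            for rec in geom.side_atoms:
                pairs.append((idx(rec.ref3), idx(rec.name)))
            if i + 1 < self.n_residues:
                pairs.append((idx("C"), self._index[(i + 1, "N")]))
        return pairs

    # -- construction --------------------------------------------------

    def _seed_initial(self) -> None:
        """Place the virtual C anchor and the first N-CA pair."""
        g0 = self.residues[0]
        n0 = np.zeros(3)
        ca0 = np.array([g0.bond_n_ca, 0.0, 0.0])
        a = g0.angle_c_n_ca
        c_prev = n0 + g0.bond_c_n * np.array([np.cos(a), np.sin(a), 0.0])
        self._c_prev = c_prev
        self.coords[self._index[(0, "N")]] = n0
        self.coords[self._index[(0, "CA")]] = ca0

    def _rebuild_residue(self, i: int, keep_next: bool) -> None:
        geom = self.residues[i]
        idx = self._index
        c_prev = self._c_prev if i == 0 else self.coords[idx[(i - 1, "C")]]
        n_i = self.coords[idx[(i, "N")]]
        ca_i = self.coords[idx[(i, "CA")]]

        c_i = place_atom(c_prev, n_i, ca_i, geom.bond_ca_c, geom.angle_n_ca_c, self._phi[i])
        self.coords[idx[(i, "C")]] = c_i
        if geom.has_cb:
            self.coords[idx[(i, "CB")]] = place_atom(
                c_i, n_i, ca_i, geom.bond_ca_cb, geom.angle_n_ca_cb, geom.dihedral_cb
            )
        self._rebuild_side_chain(i)
        self.coords[idx[(i, "O")]] = place_atom(
            n_i, ca_i, c_i, geom.bond_c_o, geom.angle_ca_c_o, wrap_angle(self._psi[i] - np.pi)
        )
        if keep_next:
            return
        n_next = place_atom(n_i, ca_i, c_i, geom.bond_c_n, geom.angle_ca_c_n, self._psi[i])
        if i + 1 < self.n_residues:
            g_next = self.residues[i + 1]
            ca_next = place_atom(ca_i, c_i, n_next, g_next.bond_n_ca, g_next.angle_c_n_ca, self._omega[i])
            self.coords[idx[(i + 1, "N")]] = n_next
            self.coords[idx[(i + 1, "CA")]] = ca_next
        else:
            g_next = geom
            ca_next = place_atom(ca_i, c_i, n_next, g_next.bond_n_ca, g_next.angle_c_n_ca, self._omega[i])
            self._n_next = n_next
            self._ca_next = ca_next

    def _rebuild_side_chain(self, i: int) -> None:
        geom = self.residues[i]
        if not geom.side_atoms:
            return
        idx = self._index
        chi = self._chi[i]
        for rec in geom.side_atoms:
            torsion = rec.offset if rec.chi_index is None else wrap_angle(chi[rec.chi_index] + rec.offset)
            self.coords[idx[(i, rec.name)]] = place_atom(
                self.coords[idx[(i, rec.ref1)]],
                self.coords[idx[(i, rec.ref2)]],
                self.coords[idx[(i, rec.ref3)]],
                rec.bond,
                rec.angle,
                torsion,
            )

    def rebuild_span(self, start: int, end: int, keep_end: bool = True) -> None:
        """Recompute atoms of residues ``start..end`` from internal coords.

        With ``keep_end=True`` the N/CA of residue ``end + 1`` (or the
        virtual end anchors) are left untouched: the caller guarantees
        closure there, as fixed-end moves do.
        """
        for i in range(start, end + 1):
            self._rebuild_residue(i, keep_next=(keep_end and i == end))
        self.version += 1

    def refresh(self) -> None:
        """Re-derive Cartesian coordinates if any torsion edit is pending."""
        if self._dirty_from is None:
            return
        start = self._dirty_from
        self._dirty_from = None
        self.rebuild_span(start, self.n_residues - 1, keep_end=False)

    @property
    def dirty(self) -> bool:
        return self._dirty_from is not None

    # -- torsion edits -------------------------------------------------

    def _mark_dirty(self, res: int) -> None:
        self._dirty_from = res if self._dirty_from is None else min(self._dirty_from, res)

    def set_phi(self, res: int, value: float) -> None:
        self._phi[res] = wrap_angle(value)
        self._mark_dirty(res)

    def set_psi(self, res: int, value: float) -> None:
        self._psi[res] = wrap_angle(value)
        self._mark_dirty(res)

    def set_chi(self, res: int, k: int, value: float) -> None:
        self._chi[res][k] = wrap_angle(value)
        self._mark_dirty(res)

    def apply_torsion_updates(self, updates: dict, start: int, end: int, keep_end: bool = True):
        """Set torsions and rebuild only residues ``start..end``.

        ``updates`` maps ``("phi", i)`` / ``("psi", i)`` / ``("chi", i, k)``
        to new values (rad).  Returns an undo record restoring the prior
        state bit-exactly via :meth:`restore`.
        """
        self.refresh()
        undo = self.snapshot(start, end)
        for key, value in updates.items():
            kind, i = key[0], key[1]
            if kind == "phi":
                self._phi[i] = wrap_angle(value)
            elif kind == "psi":
                self._psi[i] = wrap_angle(value)
            elif kind == "chi":
                self._chi[i][key[2]] = wrap_angle(value)
            else:
                raise KeyError(f"unknown torsion kind {kind!r}")
        self.rebuild_span(start, end, keep_end=keep_end)
        return undo

    def snapshot(self, start: int, end: int) -> dict:
        """State needed to undo edits touching residues ``start..end``
        (plus the N/CA anchors of the following residue and the virtual
        end anchors, which pivot rebuilds may move)."""
        self.refresh()
        sel = (self.atom_res >= start) & (self.atom_res <= end + 1)
        snap = {
            "start": start,
            "end": end,
            "atom_sel": np.where(sel)[0],
            "phi": self._phi.copy(),
            "psi": self._psi.copy(),
            "chi": [c.copy() for c in self._chi],
            "version": self.version,
            "virtuals": (self._c_prev.copy(), self._n_next.copy(), self._ca_next.copy()),
        }
        snap["coords"] = self.coords[snap["atom_sel"]].copy()
        return snap

    def restore(self, snap: dict) -> None:
        self._phi[:] = snap["phi"]
        self._psi[:] = snap["psi"]
        for c, old in zip(self._chi, snap["chi"]):
            c[:] = old
        self.coords[snap["atom_sel"]] = snap["coords"]
        self._c_prev, self._n_next, self._ca_next = (v.copy() for v in snap["virtuals"])
        self._dirty_from = None
        self.version = snap["version"]

    # -- measurement ---------------------------------------------------

    def _atom_or_virtual(self, res: int, name: str) -> np.ndarray:
        if res < 0:
            return self._c_prev
        if res >= self.n_residues:
            return {"N": self._n_next, "CA": self._ca_next}[name]
        return self.coords[self._index[(res, name)]]

    def measure_phi(self, i: int) -> float:
        self.refresh()
        return dihedral(
            self._atom_or_virtual(i - 1, "C"),
            self.coords[self._index[(i, "N")]],
            self.coords[self._index[(i, "CA")]],
            self.coords[self._index[(i, "C")]],
        )

    def measure_psi(self, i: int) -> float:
        self.refresh()
        return dihedral(
            self.coords[self._index[(i, "N")]],
            self.coords[self._index[(i, "CA")]],
            self.coords[self._index[(i, "C")]],
            self._atom_or_virtual(i + 1, "N"),
        )

    def measure_omega(self, i: int) -> float:
        self.refresh()
        return dihedral(
            self.coords[self._index[(i, "CA")]],
            self.coords[self._index[(i, "C")]],
            self._atom_or_virtual(i + 1, "N"),
            self._atom_or_virtual(i + 1, "CA"),
        )

    def measure_chi(self, i: int) -> np.ndarray:
        self.refresh()
        geom = self.residues[i]
        vals = []
        for quad in geom.chi_atoms:
            pts = [self.coords[self._index[(i, nm)]] for nm in quad]
            vals.append(dihedral(*pts))
        return np.asarray(vals)

    def check_geometry(self, tol: float = 1e-9) -> float:
        """Max absolute deviation of bond lengths/angles from the stored
        rigid geometry over the whole backbone (A and rad mixed)."""
        self.refresh()
        dev = 0.0
        for i, geom in enumerate(self.residues):
            n = self.coords[self._index[(i, "N")]]
            ca = self.coords[self._index[(i, "CA")]]
            c = self.coords[self._index[(i, "C")]]
            dev = max(dev, abs(np.linalg.norm(ca - n) - geom.bond_n_ca))
            dev = max(dev, abs(np.linalg.norm(c - ca) - geom.bond_ca_c))
            dev = max(dev, abs(bond_angle(n, ca, c) - geom.angle_n_ca_c))
            if i + 1 < self.n_residues:
                n2 = self.coords[self._index[(i + 1, "N")]]
                ca2 = self.coords[self._index[(i + 1, "CA")]]
                g2 = self.residues[i + 1]
                dev = max(dev, abs(np.linalg.norm(n2 - c) - geom.bond_c_n))
                dev = max(dev, abs(bond_angle(ca, c, n2) - geom.angle_ca_c_n))
                dev = max(dev, abs(bond_angle(c, n2, ca2) - g2.angle_c_n_ca))
                dev = max(dev, abs(wrap_angle(self.measure_omega(i) - self._omega[i])))
        return dev

    def copy(self) -> "BackboneChain":
        new = object.__new__(BackboneChain)
        new.residues = list(self.residues)
        new._phi = self._phi.copy()
        new._psi = self._psi.copy()
        new._omega = self._omega.copy()
        new._chi = [c.copy() for c in self._chi]
        new.atom_names = list(self.atom_names)
        new.atom_res = self.atom_res.copy()
        new.atom_elements = self.atom_elements.copy()
        new._index = dict(self._index)
        new.coords = self.coords.copy()
        new._c_prev = self._c_prev.copy()
        new._n_next = self._n_next.copy()
        new._ca_next = self._ca_next.copy()
        new._dirty_from = self._dirty_from
        new.version = self.version
        new.metadata = dict(self.metadata)
        return new

    # -- alternate constructor ----------------------------------------

    @classmethod
    def from_cartesian(
        cls,
        residue_names: list[str],
        atom_names: list[list[str]],
        coords: list[np.ndarray],
        table: GeometryTable | None = None,
    ) -> "BackboneChain":
        """Build a chain from per-residue atom coordinates.

        Backbone and side-chain bond lengths/angles are measured from
        the input and held rigid thereafter; torsions are measured as
        the chain's internal coordinates.  Missing backbone atoms raise
        ``ValueError`` naming the residue.
        """
        table = table or GeometryTable.default()
        n = len(residue_names)
        pos: list[dict[str, np.ndarray]] = []
        for i, (rname, names, xyz) in enumerate(zip(residue_names, atom_names, coords)):
            d = {nm: np.asarray(x, float) for nm, x in zip(names, xyz)}
            for req in ("N", "CA", "C", "O"):
                if req not in d:
                    raise ValueError(f"residue {i + 1} ({rname}): missing backbone atom {req}")
            pos.append(d)

        residues: list[ResidueGeometry] = []
        chi: list[np.ndarray] = []
        for i, rname in enumerate(residue_names):
            ideal = table.residue(rname)
            d = pos[i]
            n_i, ca_i, c_i, o_i = d["N"], d["CA"], d["C"], d["O"]
            kw = dict(
                bond_n_ca=float(np.linalg.norm(ca_i - n_i)),
                bond_ca_c=float(np.linalg.norm(c_i - ca_i)),
                bond_c_o=float(np.linalg.norm(o_i - c_i)),
                angle_n_ca_c=bond_angle(n_i, ca_i, c_i),
                angle_ca_c_o=bond_angle(ca_i, c_i, o_i),
            )
            if i + 1 < n:
                n2, ca2 = pos[i + 1]["N"], pos[i + 1]["CA"]
                kw["bond_c_n"] = float(np.linalg.norm(n2 - c_i))
                kw["angle_ca_c_n"] = bond_angle(ca_i, c_i, n2)
            if i > 0:
                c_prev = pos[i - 1]["C"]
                kw["angle_c_n_ca"] = bond_angle(c_prev, n_i, ca_i)
            if ideal.has_cb:
                if "CB" not in d:
                    raise ValueError(f"residue {i + 1} ({rname}): missing CB")
                cb = d["CB"]
                kw["bond_ca_cb"] = float(np.linalg.norm(cb - ca_i))
                kw["angle_n_ca_cb"] = bond_angle(n_i, ca_i, cb)
                kw["dihedral_cb"] = dihedral(c_i, n_i, ca_i, cb)
            chi_vals = np.asarray(
                [dihedral(*(d[nm] for nm in quad)) for quad in ideal.chi_atoms]
            )
            side = []
            for rec in ideal.side_atoms:
                if rec.name not in d:
                    raise ValueError(f"residue {i + 1} ({rname}): missing side-chain atom {rec.name}")
                tors = dihedral(d[rec.ref1], d[rec.ref2], d[rec.ref3], d[rec.name])
                offset = tors if rec.chi_index is None else wrap_angle(tors - chi_vals[rec.chi_index])
                side.append(
                    SideChainAtom(
                        rec.name, rec.ref1, rec.ref2, rec.ref3,
                        float(np.linalg.norm(d[rec.name] - d[rec.ref3])),
                        bond_angle(d[rec.ref2], d[rec.ref3], d[rec.name]),
                        rec.chi_index, float(offset),
                    )
                )
            residues.append(replace(ideal, side_atoms=tuple(side), **kw))
            chi.append(chi_vals)

        # torsions; phi of the first residue is re-measured against the
        # chain's own virtual C anchor after the rebuild below
        phi = np.zeros(n)
        psi = np.zeros(n)
        omega = np.full(n, np.pi)
        for i in range(n):
            if i > 0:
                phi[i] = dihedral(pos[i - 1]["C"], pos[i]["N"], pos[i]["CA"], pos[i]["C"])
            if i + 1 < n:
                psi[i] = dihedral(pos[i]["N"], pos[i]["CA"], pos[i]["C"], pos[i + 1]["N"])
                omega[i] = dihedral(pos[i]["CA"], pos[i]["C"], pos[i + 1]["N"], pos[i + 1]["CA"])
            else:
                # anchor the last psi on the carbonyl oxygen (O is anti to N)
                psi[i] = wrap_angle(dihedral(pos[i]["N"], pos[i]["CA"], pos[i]["C"], pos[i]["O"]) + np.pi)

        chain = cls(residues, phi, psi, omega, chi)
        # re-anchor the rebuilt chain onto the input coordinates
        from .geometry import superpose, transform_points

        ref_pts = np.array([pos[0]["N"], pos[0]["CA"], pos[0]["C"]])
        mob_pts = np.array([chain.coord(0, "N"), chain.coord(0, "CA"), chain.coord(0, "C")])
        _, t = superpose(mob_pts, ref_pts)
        chain.coords = transform_points(t, chain.coords)
        chain._c_prev = transform_points(t, chain._c_prev)
        chain._n_next = transform_points(t, chain._n_next)
        chain._ca_next = transform_points(t, chain._ca_next)
        # the virtual C anchor defines the phi reference of residue 0:
        # re-measure against it, then rebuild so coordinates agree
        chain._phi[0] = chain.measure_phi(0)
        chain.rebuild_span(0, n - 1, keep_end=False)
        return chain


def build_chain_from_internal(
    sequence,
    phi,
    psi,
    omega=None,
    chi=None,
    table: GeometryTable | None = None,
) -> BackboneChain:
    """Construct a chain from residue names and torsions.

    ``sequence`` may be one-letter codes (string or list) or
    three-letter names.  ``omega`` defaults to trans (pi) everywhere;
    ``chi`` defaults to all-trans side chains.
    """
    table = table or GeometryTable.default()
    residues = [table.residue(code) for code in sequence]
    n = len(residues)
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    if len(phi) != n or len(psi) != n:
        raise ValueError(f"torsion count mismatch: {n} residues, {len(phi)} phi / {len(psi)} psi")
    if omega is None:
        omega = np.array([g.omega for g in residues])
    if chi is None:
        chi = [np.full(g.n_chi, np.pi) for g in residues]
    return BackboneChain(residues, phi, psi, np.asarray(omega, float), chi)
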