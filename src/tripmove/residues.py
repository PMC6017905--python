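"""Residue geometry tables.

Loads the idealized bond-length/bond-angle data shipped with the
package and exposes it as :class:`ResidueGeometry` records.  Geometry
is held rigid during sampling (the rigid-geometry assumption): bond
lengths, bond angles and the peptide torsion omega are constants; only
phi/psi and the side-chain chi torsions are degrees of freedom.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = ["SideChainAtom", "ResidueGeometry", "GeometryTable", "ONE_TO_THREE", "THREE_TO_ONE"]

ONE_TO_THREE = {
    "G": "GLY", "A": "ALA", "S": "SER", "C": "CYS", "V": "VAL",
    "T": "THR", "L": "LEU", "I": "ILE", "D": "ASP", "N": "ASN",
    "E": "GLU", "Q": "GLN", "M": "MET", "K": "LYS", "F": "PHE",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

_TORSION_RE = re.compile(r"^chi(\d+)([+-]\d+(?:\.\d+)?)?$")


@dataclass(frozen=True)
class SideChainAtom:
    """Z-matrix-style placement record for one side-chain atom.

    ``torsion`` is resolved at build time as ``chi[chi_index] + offset``
    when ``chi_index`` is not None, else the constant ``offset`` (rad).
    """

    name: str
    ref1: str
    ref2: str
    ref3: str
    bond: float
    angle: float  # rad
    chi_index: int | None
    offset: float  # rad

    @property
    def element(self) -> str:
        return self.name[0]


@dataclass(frozen=True)
class ResidueGeometry:
    """Rigid internal geometry of one residue type (lengths A, angles rad)."""

    name: str
    bond_n_ca: float
    bond_ca_c: float
    bond_c_n: float
    bond_c_o: float
    bond_ca_cb: float
    angle_c_n_ca: float
    angle_n_ca_c: float
    angle_ca_c_n: float
    angle_ca_c_o: float
    angle_n_ca_cb: float
    dihedral_cb: float
    omega: float
    side_atoms: tuple[SideChainAtom, ...]
    chi_atoms: tuple[tuple[str, str, str, str], ...]

    def __post_init__(self):
        for val in (self.bond_n_ca, self.bond_ca_c, self.bond_c_n, self.bond_c_o, self.bond_ca_cb):
            if val <= 0:
                raise ValueError(f"{self.name}: non-positive bond length")
        for val in (self.angle_c_n_ca, self.angle_n_ca_c, self.angle_ca_c_n,
                    self.angle_ca_c_o, self.angle_n_ca_cb):
            if not 0.0 < val < np.pi:
                raise ValueError(f"{self.name}: bond angle outside (0, pi)")

    @property
    def has_cb(self) -> bool:
        return self.name != "GLY"

    @property
    def n_chi(self) -> int:
        return len(self.chi_atoms)

    @property
    def atom_names(self) -> list[str]:
        names = ["N", "CA", "C", "O"]
        if self.has_cb:
            names.append("CB")
        names.extend(a.name for a in self.side_atoms)
        return names


def _parse_torsion(spec) -> tuple[int | None, float]:
    if isinstance(spec, (int, float)):
        return None, float(np.deg2rad(spec))
    m = _TORSION_RE.match(str(spec))
    if not m:
        raise ValueError(f"bad torsion spec {spec!r}")
    chi_index = int(m.group(1)) - 1
    offset = float(np.deg2rad(float(m.group(2)))) if m.group(2) else 0.0
    return chi_index, offset


class GeometryTable:
    """Residue-geometry source backed by a YAML data file."""

    def __init__(self, raw: dict):
        self._backbone = raw["backbone"]
        self._residues = raw["residues"]
        self._cache: dict[str, ResidueGeometry] = {}

    @classmethod
    def default(cls) -> "GeometryTable":
        path = resources.files("tripmove.data").joinpath("residue_geometry.yaml")
        with path.open() as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def from_file(cls, path) -> "GeometryTable":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @property
    def known_residues(self) -> list[str]:
        return sorted(self._residues)

    def residue(self, name: str) -> ResidueGeometry:
        name = name.upper()
        if len(name) == 1:
            if name not in ONE_TO_THREE:
                raise KeyError(f"unknown residue code {name!r}")
            name = ONE_TO_THREE[name]
        if name in self._cache:
            return self._cache[name]
        if name not in self._residues:
            raise KeyError(f"unknown residue name {name!r}")
        bb = self._backbone
        entry = self._residues[name]
        side_atoms = []
        for rec in entry.get("atoms", []):
            aname, r1, r2, r3, bond, angle, torsion = rec
            chi_index, offset = _parse_torsion(torsion)
            side_atoms.append(SideChainAtom(aname, r1, r2, r3, float(bond),
                                            float(np.deg2rad(angle)), chi_index, offset))
        geom = ResidueGeometry(
            name=name,
            bond_n_ca=bb["bond_N_CA"],
            bond_ca_c=bb["bond_CA_C"],
            bond_c_n=bb["bond_C_N"],
            bond_c_o=bb["bond_C_O"],
            bond_ca_cb=bb["bond_CA_CB"],
            angle_c_n_ca=float(np.deg2rad(bb["angle_C_N_CA"])),
            angle_n_ca_c=float(np.deg2rad(bb["angle_N_CA_C"])),
            angle_ca_c_n=float(np.deg2rad(bb["angle_CA_C_N"])),
            angle_ca_c_o=float(np.deg2rad(bb["angle_CA_C_O"])),
            angle_n_ca_cb=float(np.deg2rad(bb["angle_N_CA_CB"])),
            dihedral_cb=float(np.deg2rad(bb["dihedral_C_N_CA_CB"])),
            omega=float(np.deg2rad(bb["omega_default"])),
            side_atoms=tuple(side_atoms),
            chi_atoms=tuple(tuple(q) for q in entry.get("chi_atoms", [])),
        )
        self._cache[name] = geom
        return geom
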