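"""Deterministic polypeptide fixtures built from idealized geometry."""

from __future__ import annotations

import numpy as np

from .chain import BackboneChain, build_chain_from_internal
from .residues import GeometryTable

__all__ = ["PHI_PSI_PRESETS", "build_polypeptide_fixture"]

# (phi, psi) in degrees
PHI_PSI_PRESETS = {
    "helix": (-57.0, -47.0),  # canonical right-handed alpha helix
    "extended": (-135.0, 135.0),  # beta-strand-like extended chain
    "ppii": (-75.0, 145.0),  # polyproline-II-like coil
}


def build_polypeptide_fixture(
    sequence,
    phi_psi_preset: str = "helix",
    phi=None,
    psi=None,
    table: GeometryTable | None = None,
) -> BackboneChain:
    """Idealized-geometry chain at preset or custom torsions.

    ``phi_psi_preset`` is one of ``helix``, ``extended``, ``ppii`` or
    ``custom`` (then ``phi``/``psi`` arrays are required, in radians).
    Identical inputs always give bit-identical chains.
    """
    n = len(sequence)
    if phi_psi_preset == "custom":
        if phi is None or psi is None:
            raise ValueError("custom preset requires explicit phi and psi arrays")
    else:
        if phi_psi_preset not in PHI_PSI_PRESETS:
            raise KeyError(f"unknown preset {phi_psi_preset!r}")
        p, s = PHI_PSI_PRESETS[phi_psi_preset]
        phi = np.full(n, np.deg2rad(p))
        psi = np.full(n, np.deg2rad(s))
    return build_chain_from_internal(sequence, phi, psi, table=table)
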