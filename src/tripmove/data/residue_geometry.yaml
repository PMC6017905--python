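# Idealized heavy-atom geometry for polypeptide construction.
#
# Backbone bond lengths (A) and angles (deg) are Engh & Huber-like
# standard values; side-chain placements use idealized tetrahedral /
# trigonal values in the spirit of chemical-component dictionary
# templates.  The model treats all of these as rigid during sampling:
# only the torsions marked chi* (and the backbone phi/psi) vary.
#
# Side-chain atom records: [name, ref1, ref2, ref3, bond, angle, torsion]
# The atom is bonded to ref3 with the given bond length, forms the given
# angle ref2-ref3-atom, and the dihedral ref1-ref2-ref3-atom is either a
# constant (deg) or the string "chiK" / "chiK+offset" / "chiK-offset".
# chi_atoms lists the defining quadruple of each variable side-chain
# torsion in order chi1, chi2, ...

backbone:
  bond_N_CA: 1.458
  bond_CA_C: 1.525
  bond_C_N: 1.329
  bond_C_O: 1.231
  bond_CA_CB: 1.521
  angle_C_N_CA: 121.7
  angle_N_CA_C: 111.2
  angle_CA_C_N: 116.2
  angle_CA_C_O: 120.8
  angle_N_CA_CB: 110.4
  # Dihedral C(i)-N(i)-CA(i)-CB(i), fixed by L-amino-acid chirality.
  dihedral_C_N_CA_CB: 120.0
  omega_default: 180.0

residues:
  GLY:
    atoms: []
    chi_atoms: []
  ALA:
    atoms: []
    chi_atoms: []
  SER:
    atoms:
      - [OG, N, CA, CB, 1.417, 110.8, chi1]
    chi_atoms:
      - [N, CA, CB, OG]
  CYS:
    atoms:
      - [SG, N, CA, CB, 1.808, 114.4, chi1]
    chi_atoms:
      - [N, CA, CB, SG]
  VAL:
    atoms:
      - [CG1, N, CA, CB, 1.521, 110.5, chi1]
      - [CG2, N, CA, CB, 1.521, 110.5, chi1+122.0]
    chi_atoms:
      - [N, CA, CB, CG1]
  THR:
    atoms:
      - [OG1, N, CA, CB, 1.433, 109.6, chi1]
      - [CG2, N, CA, CB, 1.521, 110.5, chi1+122.0]
    chi_atoms:
      - [N, CA, CB, OG1]
  LEU:
    atoms:
      - [CG, N, CA, CB, 1.530, 116.3, chi1]
      - [CD1, CA, CB, CG, 1.521, 110.7, chi2]
      - [CD2, CA, CB, CG, 1.521, 110.7, chi2+122.0]
    chi_atoms:
      - [N, CA, CB, CG]
      - [CA, CB, CG, CD1]
  ILE:
    atoms:
      - [CG1, N, CA, CB, 1.530, 110.4, chi1]
      - [CG2, N, CA, CB, 1.521, 110.5, chi1-122.0]
      - [CD1, CA, CB, CG1, 1.513, 113.8, chi2]
    chi_atoms:
      - [N, CA, CB, CG1]
      - [CA, CB, CG1, CD1]
  ASP:
    atoms:
      - [CG, N, CA, CB, 1.516, 112.6, chi1]
      - [OD1, CA, CB, CG, 1.249, 118.4, chi2]
      - [OD2, CA, CB, CG, 1.249, 118.4, chi2+180.0]
    chi_atoms:
      - [N, CA, CB, CG]
      - [CA, CB, CG, OD1]
  ASN:
    atoms:
      - [CG, N, CA, CB, 1.516, 112.6, chi1]
      - [OD1, CA, CB, CG, 1.231, 120.8, chi2]
      - [ND2, CA, CB, CG, 1.328, 116.4, chi2+180.0]
    chi_atoms:
      - [N, CA, CB, CG]
      - [CA, CB, CG, OD1]
  GLU:
    atoms:
      - [CG, N, CA, CB, 1.520, 114.1, chi1]
      - [CD, CA, CB, CG, 1.516, 112.6, chi2]
      - [OE1, CB, CG, CD, 1.249, 118.4, chi3]
      - [OE2, CB, CG, CD, 1.249, 118.4, chi3+180.0]
    chi_atoms:
      - [N, CA, CB, CG]
      - [CA, CB, CG, CD]
      - [CB, CG, CD, OE1]
  GLN:
    atoms:
      - [CG, N, CA, CB, 1.520, 114.1, chi1]
      - [CD, CA, CB, CG, 1.516, 112.6, chi2]
      - [OE1, CB, CG, CD, 1.231, 120.8, chi3]
      - [NE2, CB, CG, CD, 1.328, 116.4, chi3+180.0]
    chi_atoms:
      - [N, CA, CB, CG]
      - [CA, CB, CG, CD]
      - [CB, CG, CD, OE1]
  MET:
    atoms:
      - [CG, N, CA, CB, 1.520, 114.1, chi1]
      - [SD, CA, CB, CG, 1.803, 112.7, chi2]
      - [CE, CB, CG, SD, 1.791, 100.9, chi3]
    chi_atoms:
      - [N, CA, CB, CG]
      - [CA, CB, CG, SD]
      - [CB, CG, SD, CE]
  LYS:
    atoms:
      - [CG, N, CA, CB, 1.520, 114.1, chi1]
      - [CD, CA, CB, CG, 1.520, 111.3, chi2]
      - [CE, CB, CG, CD, 1.520, 111.3, chi3]
      - [NZ, CG, CD, CE, 1.489, 111.9, chi4]
    chi_atoms:
      - [N, CA, CB, CG]
      - [CA, CB, CG, CD]
      - [CB, CG, CD, CE]
      - [CG, CD, CE, NZ]
  PHE:
    atoms:
      - [CG, N, CA, CB, 1.502, 113.8, chi1]
      - [CD1, CA, CB, CG, 1.384, 120.7, chi2]
      - [CD2, CA, CB, CG, 1.384, 120.7, chi2+180.0]
      - [CE1, CB, CG, CD1, 1.382, 120.7, 180.0]
      - [CE2, CB, CG, CD2, 1.382, 120.7, 180.0]
      - [CZ, CG, CD1, CE1, 1.382, 120.0, 0.0]
    chi_atoms:
      - [N, CA, CB, CG]
      - [CA, CB, CG, CD1]
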