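"""Atom typing tables shared by interaction detection and the energy surrogate.

Classification is by (residue name, atom name) under PDB naming conventions;
reduced toy residues built by :mod:`bindmode.synthetic_data` use the same
names, so a single table serves both real and synthetic structures.
"""

from __future__ import annotations

from .structure_io import Atom, Structure

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HIP",
    "HID", "HIE", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}

# Heavy-atom hydrogen-bond donors (backbone N added for every amino acid).
SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"}, "HID": {"ND1"}, "HIE": {"NE2"},
    "HIP": {"ND1", "NE2"}, "TRP": {"NE1"}, "CYS": {"SG"},
}

# Heavy-atom hydrogen-bond acceptors (backbone O/OXT added for every AA).
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "HID": {"NE2"}, "HIE": {"ND1"},
    "MET": {"SD"}, "CYS": {"SG"},
}

# Positively charged groups usable in salt bridges.
CATION_ATOMS = {
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIP": {"ND1", "NE2"},
}

# Negatively charged oxygens (carboxylates; nucleotide phosphates).
PHOSPHATE_O = {"O1A", "O2A", "O3A", "O1B", "O2B", "O3B", "O1G", "O2G", "O3G"}
ANION_ATOMS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "GTP": set(PHOSPHATE_O), "GDP": {"O1A", "O2A", "O3A", "O1B", "O2B", "O3B"},
    "ATP": set(PHOSPHATE_O), "ADP": {"O1A", "O2A", "O3A", "O1B", "O2B", "O3B"},
}

GAMMA_PHOSPHATE = {"PG", "O1G", "O2G", "O3G"}

AROMATIC_RINGS: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "CD2", "NE1", "CE2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HID": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HIE": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HIP": [("CG", "ND1", "CD2", "CE1", "NE2")],
}

# Formal charges for the surrogate electrostatics (per atom, elementary units).
FORMAL_CHARGES: dict[tuple[str, str], float] = {}
for _res, _names in (("ASP", ("OD1", "OD2")), ("GLU", ("OE1", "OE2"))):
    for _n in _names:
        FORMAL_CHARGES[(_res, _n)] = -0.5
FORMAL_CHARGES[("LYS", "NZ")] = 1.0
for _n in ("NH1", "NH2"):
    FORMAL_CHARGES[("ARG", _n)] = 0.5
for _n in ("ND1", "NE2"):
    FORMAL_CHARGES[("HIP", _n)] = 0.5
for _res in ("GTP", "ATP"):
    for _n in PHOSPHATE_O:
        FORMAL_CHARGES[(_res, _n)] = -1.0 / 3.0
for _res in ("GDP", "ADP"):
    for _n in ("O1A", "O2A", "O3A", "O1B", "O2B", "O3B"):
        FORMAL_CHARGES[(_res, _n)] = -1.0 / 3.0
FORMAL_CHARGES[("MG", "MG")] = 2.0


def is_donor(atom: Atom) -> bool:
    if not atom.is_heavy:
        return False
    if atom.name == "N" and atom.residue_name in STANDARD_AA:
        return True
    return atom.name in SIDECHAIN_DONORS.get(atom.residue_name, ())


def is_acceptor(atom: Atom) -> bool:
    if not atom.is_heavy:
        return False
    if atom.name in ("O", "OXT") and atom.residue_name in STANDARD_AA:
        return True
    if atom.residue_name in ("GTP", "GDP", "ATP", "ADP") and atom.element == "O":
        return True
    return atom.name in SIDECHAIN_ACCEPTORS.get(atom.residue_name, ())


def _his_is_protonated(structure: Structure, residue_key: tuple) -> bool:
    """HIS counts as charged only with both ring protons present (or res HIP)."""
    names = {a.name for a in structure.atoms if a.residue_key == residue_key}
    return "HD1" in names and "HE2" in names


def is_cation(atom: Atom, structure: Structure | None = None) -> bool:
    if not atom.is_heavy:
        return False
    if atom.residue_name == "MG" or (atom.name == "MG" and atom.element == "MG"):
        return True
    if atom.residue_name == "HIS" and atom.name in ("ND1", "NE2"):
        return structure is not None and _his_is_protonated(
            structure, atom.residue_key)
    return atom.name in CATION_ATOMS.get(atom.residue_name, ())


def is_anion(atom: Atom) -> bool:
    if not atom.is_heavy:
        return False
    if atom.name == "OXT":
        return True
    return atom.name in ANION_ATOMS.get(atom.residue_name, ())


def is_apolar(atom: Atom) -> bool:
    """Lipophilic surrogate class: carbon and sulfur heavy atoms."""
    return atom.element.upper() in ("C", "S")


def formal_charge(atom: Atom) -> float:
    if atom.name == "OXT":
        return -0.5
    return FORMAL_CHARGES.get((atom.residue_name, atom.name), 0.0)
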