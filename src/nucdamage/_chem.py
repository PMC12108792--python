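"""Bundled chemical reference data.

Idealized heavy-atom base templates (local frame: glycosidic N at origin,
C1' attachment along -x, ring in the xy-plane), van-der-Waals radii, and
donor/acceptor/charge typing tables used by contact counting.
"""

from __future__ import annotations

import numpy as np

# --- idealized base templates (Angstrom, heavy atoms only) -----------------
# Pyrimidine ring: regular hexagon, bond 1.38 A, N1 at the origin.
_PYR_RING = {
    "N1": (0.000, 0.000, 0.0),
    "C2": (0.690, 1.195, 0.0),
    "N3": (2.070, 1.195, 0.0),
    "C4": (2.760, 0.000, 0.0),
    "C5": (2.070, -1.195, 0.0),
    "C6": (0.690, -1.195, 0.0),
}

# Purine: fused pentagon (N9 C8 N7 C5 C4) + hexagon (C4 C5 C6 N1 C2 N3).
_PUR_RING = {
    "N9": (0.000, 0.000, 0.0),
    "C8": (0.806, 1.109, 0.0),
    "N7": (2.109, 0.685, 0.0),
    "C5": (2.109, -0.685, 0.0),
    "C4": (0.806, -1.109, 0.0),
    "C6": (3.138, -1.602, 0.0),
    "N1": (2.856, -2.953, 0.0),
    "C2": (1.545, -3.384, 0.0),
    "N3": (0.513, -2.455, 0.0),
}

BASE_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "U": {**_PYR_RING, "O2": (0.075, 2.260, 0.0), "O4": (3.990, 0.000, 0.0)},
    "T": {**_PYR_RING, "O2": (0.075, 2.260, 0.0), "O4": (3.990, 0.000, 0.0),
          "C7": (2.820, -2.490, 0.0)},
    "C": {**_PYR_RING, "O2": (0.075, 2.260, 0.0), "N4": (3.720, 0.000, 0.0)},
    "A": {**_PUR_RING, "N6": (4.410, -1.180, 0.0)},
    "G": {**_PUR_RING, "O6": (4.410, -1.180, 0.0), "N2": (1.270, -4.700, 0.0)},
}

# Glycosidic attachment: N (origin) bonded to C1' at (-GLYCOSIDIC_BOND, 0, 0).
GLYCOSIDIC_BOND = 1.47

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1", "U": "N1"}
# in-plane orientation reference atom (positive template y for every base)
ORIENT_ATOM = {"A": "C8", "G": "C8", "C": "C2", "T": "C2", "U": "C2"}

RESNAME_OF_BASE = {"A": "DA", "T": "DT", "G": "DG", "C": "DC", "U": "DU"}
BASE_OF_RESNAME = {v: k for k, v in RESNAME_OF_BASE.items()}
BASE_OF_RESNAME.update({"A": "A", "T": "T", "G": "G", "C": "C", "U": "U",
                        "ADE": "A", "THY": "T", "GUA": "G", "CYT": "C", "URA": "U"})

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}

# Backbone + sugar atom names (primes canonical); everything else in a
# nucleotide is considered a base atom. CEN is the base-centroid pseudo-atom.
BACKBONE_SUGAR_NAMES = {
    "P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
    # dRP cap atoms (suffixed copies of the excised sugar)
    "PR", "O5R", "C5R", "C4R", "O4R", "C3R", "C2R", "C1R",
}


def base_atoms(residue) -> list:
    """Atoms of a nucleotide that belong to the base (incl. CEN pseudo-atom)."""
    return [a for a in residue.atoms
            if a.name not in BACKBONE_SUGAR_NAMES and not a.name.startswith("H")]


def place_base_template(base: str, c1_pos: np.ndarray, e1: np.ndarray,
                        e2: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Place an idealized base in the frame (e1 = C1'->N direction, e2 =
    in-plane unit toward the orientation atom side). Returns named positions
    including a trailing CEN centroid pseudo-atom."""
    base = base.upper()
    tpl = BASE_TEMPLATES[base]
    e1 = np.asarray(e1, float) / np.linalg.norm(e1)
    e2 = np.asarray(e2, float) / np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    origin = np.asarray(c1_pos, float) + GLYCOSIDIC_BOND * e1
    out = []
    for name, (x, y, z) in tpl.items():
        out.append((name, origin + x * e1 + y * e2 + z * e3))
    cen = np.mean([p for _, p in out], axis=0)
    out.append(("CEN", cen))
    return out


# --- van der Waals radii (Angstrom) ----------------------------------------
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "FE": 1.80, "ZN": 1.39,
    "MG": 1.73, "NA": 2.27, "K": 2.75, "X": 1.70,
}


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise KeyError(f"no van-der-Waals radius for element {element!r}") from None


# --- hydrogen-bond donor / acceptor typing ---------------------------------
# Heavy-atom-only typing; community-default geometric criteria are applied
# by the caller. Backbone amide N is a donor, carbonyl O an acceptor.
PROTEIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
PROTEIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
NUC_DONORS = {
    "A": {"N6"}, "C": {"N4"}, "G": {"N1", "N2"}, "T": {"N3"}, "U": {"N3"},
}
NUC_ACCEPTORS = {
    "A": {"N1", "N3", "N7"}, "C": {"O2", "N3"}, "G": {"O6", "N3", "N7"},
    "T": {"O2", "O4"}, "U": {"O2", "O4"},
}
NUC_BACKBONE_ACCEPTORS = {"OP1", "OP2", "O1P", "O2P", "O5'", "O3'", "O4'"}

# --- salt-bridge charged groups --------------------------------------------
CATION_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
}
ANION_ATOMS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}
PHOSPHATE_ANIONS = {"OP1", "OP2", "O1P", "O2P"}

# --- hydrophobic residues ---------------------------------------------------
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "PRO", "TRP"}


def donor_atoms(residue) -> list:
    rn = residue.resname.upper()
    out = []
    if residue.kind == "amino-acid":
        named = PROTEIN_DONORS.get(rn, set())
        for a in residue.atoms:
            if a.name in named or a.name == "N":
                out.append(a)
    elif residue.kind == "nucleotide":
        base = BASE_OF_RESNAME.get(rn)
        named = NUC_DONORS.get(base, set()) if base else set()
        out.extend(a for a in residue.atoms if a.name in named)
    return out


def acceptor_atoms(residue) -> list:
    rn = residue.resname.upper()
    out = []
    if residue.kind == "amino-acid":
        named = PROTEIN_ACCEPTORS.get(rn, set())
        for a in residue.atoms:
            if a.name in named or a.name == "O":
                out.append(a)
    elif residue.kind == "nucleotide":
        base = BASE_OF_RESNAME.get(rn)
        named = NUC_ACCEPTORS.get(base, set()) if base else set()
        for a in residue.atoms:
            if a.name in named or a.name in NUC_BACKBONE_ACCEPTORS:
                out.append(a)
    return out


def cation_atoms(residue) -> list:
    named = CATION_ATOMS.get(residue.resname.upper(), set())
    return [a for a in residue.atoms if a.name in named]


def anion_atoms(residue) -> list:
    if residue.kind == "nucleotide":
        return [a for a in residue.atoms if a.name in PHOSPHATE_ANIONS]
    named = ANION_ATOMS.get(residue.resname.upper(), set())
    return [a for a in residue.atoms if a.name in named]


def apolar_carbons(residue) -> list:
    if residue.kind == "amino-acid":
        if residue.resname.upper() not in APOLAR_RESIDUES:
            return []
        return [a for a in residue.atoms
                if a.element.upper() == "C" and a.name not in {"C", "CA"}]
    if residue.kind == "nucleotide":
        # thymine methyl is the only strongly apolar DNA moiety
        return [a for a in residue.atoms if a.name in {"C7", "C5M"}]
    return []
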