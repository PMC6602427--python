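"""Shipped chemistry lookup tables.

All tables are keyed by PDB v3.3 atom naming for the 20 standard amino
acids. They drive pharmacophore typing, contact classification and SASA
normalisation; every distance rule that consumes them treats cutoffs as
inclusive (<=).
"""

# one-letter <-> three-letter codes
AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}

#: one-letter codes in alphabetical order (composition vector order)
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: column order of PSI-BLAST ASCII position-specific scoring matrices
PSSM_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Theoretical maximum accessible surface area per residue (A^2),
# Tien et al. 2013, used to normalise SASA into relative accessibility.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# van der Waals radii (A), Bondi set
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}

# single-bond covalent radii (A)
COVALENT_RADII = {"C": 0.77, "N": 0.71, "O": 0.66, "S": 1.05, "H": 0.31, "P": 1.07}

# hydrogen-bond capable side-chain atoms (heavy-atom criterion; backbone
# N/O handled by rule in code)
DONOR_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}
ACCEPTOR_ATOMS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
}

# formally charged side-chain atoms at physiological pH
POSITIVE_ATOMS = {
    "ARG": {"NE", "NH1", "NH2", "CZ"},
    "LYS": {"NZ"},
}
NEGATIVE_ATOMS = {
    "ASP": {"OD1", "OD2", "CG"},
    "GLU": {"OE1", "OE2", "CD"},
}

SULFUR_ATOMS = {"CYS": {"SG"}, "MET": {"SD"}}

# aromatic ring systems (ordered atom tuples)
AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TYR": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "HIS": [("CG", "ND1", "CE1", "NE2", "CD2")],
    "TRP": [
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ],
}

#: pharmacophore vocabulary, in the order signature pair classes are built
PHARMACOPHORES = (
    "hydrophobic",
    "aromatic",
    "donor",
    "acceptor",
    "positive",
    "negative",
    "sulfur",
    "neutral",
)

#: heavy atoms of each standard residue (backbone + side chain, no OXT)
RESIDUE_ATOMS = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "ARG": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "CYS": ["N", "CA", "C", "O", "CB", "SG"],
    "GLN": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"],
    "GLY": ["N", "CA", "C", "O"],
    "HIS": ["N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"],
    "LEU": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
    "LYS": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
    "MET": ["N", "CA", "C", "O", "CB", "CG", "SD", "CE"],
    "PHE": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["N", "CA", "C", "O", "CB", "CG", "CD"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "THR": ["N", "CA", "C", "O", "CB", "OG1", "CG2"],
    "TRP": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH"],
    "VAL": ["N", "CA", "C", "O", "CB", "CG1", "CG2"],
}


def ring_atoms(resname: str) -> set:
    """All atom names belonging to any aromatic ring of ``resname``."""
    atoms = set()
    for ring in AROMATIC_RINGS.get(resname, []):
        atoms.update(ring)
    return atoms
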