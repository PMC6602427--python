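"""Idealised side-chain templates built from internal coordinates.

Each recipe places side-chain heavy atoms by the NeRF construction from
the residue's own N-CA-CB frame, using ideal bond lengths/angles and the
most common rotamer for each chi angle. Entries are
(atom, ref1, ref2, ref3, bond A, angle deg, torsion deg): the new atom
bonds to ref3, with the ref2-ref3-atom angle and ref1-ref2-ref3-atom
torsion given. CB itself comes from the standard backbone reconstruction
(see :func:`ppiddg._geometry.ideal_cb`), so grafting is deterministic and
leaves the backbone untouched.
"""

from __future__ import annotations

import numpy as np

from ppiddg._geometry import ideal_cb, place_atom

# chi1 = -60 (gauche-) unless a residue's modal rotamer differs
SIDE_CHAIN_RECIPES = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "N", "CA", "CB", 1.42, 110.5, -60.0)],
    "CYS": [("SG", "N", "CA", "CB", 1.81, 114.0, -60.0)],
    "THR": [
        ("OG1", "N", "CA", "CB", 1.43, 109.5, -60.0),
        ("CG2", "N", "CA", "CB", 1.52, 110.5, 60.0),
    ],
    "VAL": [
        ("CG1", "N", "CA", "CB", 1.52, 110.5, 175.0),
        ("CG2", "N", "CA", "CB", 1.52, 110.5, -65.0),
    ],
    "LEU": [
        ("CG", "N", "CA", "CB", 1.53, 116.3, -60.0),
        ("CD1", "CA", "CB", "CG", 1.52, 110.5, 180.0),
        ("CD2", "CA", "CB", "CG", 1.52, 110.5, -60.0),
    ],
    "ILE": [
        ("CG1", "N", "CA", "CB", 1.53, 110.5, -60.0),
        ("CG2", "N", "CA", "CB", 1.53, 110.5, 60.0),
        ("CD1", "CA", "CB", "CG1", 1.52, 113.8, 180.0),
    ],
    "MET": [
        ("CG", "N", "CA", "CB", 1.52, 114.1, -60.0),
        ("SD", "CA", "CB", "CG", 1.80, 112.7, 180.0),
        ("CE", "CB", "CG", "SD", 1.79, 100.9, 180.0),
    ],
    "PRO": [
        ("CG", "N", "CA", "CB", 1.50, 104.5, -30.0),
        ("CD", "CA", "CB", "CG", 1.51, 105.5, 35.0),
    ],
    "PHE": [
        ("CG", "N", "CA", "CB", 1.50, 113.8, -60.0),
        ("CD1", "CA", "CB", "CG", 1.39, 120.8, 90.0),
        ("CD2", "CA", "CB", "CG", 1.39, 120.8, -90.0),
        ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", "N", "CA", "CB", 1.51, 113.8, -60.0),
        ("CD1", "CA", "CB", "CG", 1.39, 120.8, 90.0),
        ("CD2", "CA", "CB", "CG", 1.39, 120.8, -90.0),
        ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
        ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
        ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
        ("OH", "CD1", "CE1", "CZ", 1.38, 120.0, 180.0),
    ],
    "TRP": [
        ("CG", "N", "CA", "CB", 1.50, 113.8, -60.0),
        ("CD1", "CA", "CB", "CG", 1.37, 127.0, 90.0),
        ("CD2", "CA", "CB", "CG", 1.43, 126.6, -90.0),
        ("NE1", "CD2", "CG", "CD1", 1.38, 110.2, 0.0),
        ("CE2", "CG", "CD1", "NE1", 1.37, 109.0, 0.0),
        ("CE3", "CD1", "CG", "CD2", 1.40, 133.9, 180.0),
        ("CZ2", "CD1", "NE1", "CE2", 1.40, 130.1, 180.0),
        ("CZ3", "CE2", "CD2", "CE3", 1.39, 118.8, 0.0),
        ("CH2", "CD2", "CE3", "CZ3", 1.37, 121.2, 0.0),
    ],
    "HIS": [
        ("CG", "N", "CA", "CB", 1.49, 113.8, -60.0),
        ("ND1", "CA", "CB", "CG", 1.38, 122.7, -75.0),
        ("CD2", "CA", "CB", "CG", 1.35, 131.1, 105.0),
        ("CE1", "CD2", "CG", "ND1", 1.32, 105.2, 0.0),
        ("NE2", "ND1", "CG", "CD2", 1.37, 107.2, 0.0),
    ],
    "ASP": [
        ("CG", "N", "CA", "CB", 1.52, 112.6, -60.0),
        ("OD1", "CA", "CB", "CG", 1.25, 118.4, -20.0),
        ("OD2", "CA", "CB", "CG", 1.25, 118.4, 160.0),
    ],
    "ASN": [
        ("CG", "N", "CA", "CB", 1.52, 112.6, -60.0),
        ("OD1", "CA", "CB", "CG", 1.23, 120.8, -60.0),
        ("ND2", "CA", "CB", "CG", 1.33, 116.4, 120.0),
    ],
    "GLU": [
        ("CG", "N", "CA", "CB", 1.52, 114.1, -60.0),
        ("CD", "CA", "CB", "CG", 1.52, 112.6, 180.0),
        ("OE1", "CB", "CG", "CD", 1.25, 118.4, -20.0),
        ("OE2", "CB", "CG", "CD", 1.25, 118.4, 160.0),
    ],
    "GLN": [
        ("CG", "N", "CA", "CB", 1.52, 114.1, -60.0),
        ("CD", "CA", "CB", "CG", 1.52, 112.6, 180.0),
        ("OE1", "CB", "CG", "CD", 1.23, 120.8, -60.0),
        ("NE2", "CB", "CG", "CD", 1.33, 116.4, 120.0),
    ],
    "LYS": [
        ("CG", "N", "CA", "CB", 1.52, 114.1, -60.0),
        ("CD", "CA", "CB", "CG", 1.52, 111.3, 180.0),
        ("CE", "CB", "CG", "CD", 1.52, 111.3, 180.0),
        ("NZ", "CG", "CD", "CE", 1.49, 111.9, 180.0),
    ],
    "ARG": [
        ("CG", "N", "CA", "CB", 1.52, 114.1, -60.0),
        ("CD", "CA", "CB", "CG", 1.52, 111.3, 180.0),
        ("NE", "CB", "CG", "CD", 1.46, 111.8, 180.0),
        ("CZ", "CG", "CD", "NE", 1.33, 124.8, 180.0),
        ("NH1", "CD", "NE", "CZ", 1.33, 120.0, 0.0),
        ("NH2", "CD", "NE", "CZ", 1.33, 120.0, 180.0),
    ],
}


def build_side_chain(resname: str, n: np.ndarray, ca: np.ndarray,
                     c: np.ndarray, cb: np.ndarray | None = None
                     ) -> dict[str, np.ndarray]:
    """Side-chain heavy-atom coordinates for ``resname`` on a backbone frame.

    ``cb`` overrides the reconstructed CB (to preserve a crystallographic
    CB orientation when grafting). Returns an ordered ``{atom_name: xyz}``
    dict; empty for glycine, ``{"CB": ...}`` only for alanine.
    """
    if resname not in SIDE_CHAIN_RECIPES:
        raise KeyError(f"no side-chain template for residue '{resname}'")
    placed: dict[str, np.ndarray] = {
        "N": np.asarray(n, dtype=float),
        "CA": np.asarray(ca, dtype=float),
        "C": np.asarray(c, dtype=float),
    }
    out: dict[str, np.ndarray] = {}
    if resname != "GLY":
        if cb is None:
            cb = ideal_cb(placed["N"], placed["CA"], placed["C"])
        else:
            cb = np.asarray(cb, dtype=float)
        placed["CB"] = cb
        out["CB"] = cb
    for atom, r1, r2, r3, bond, angle, torsion in SIDE_CHAIN_RECIPES[resname]:
        pos = place_atom(placed[r1], placed[r2], placed[r3], bond, angle, torsion)
        placed[atom] = pos
        out[atom] = pos
    return out
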