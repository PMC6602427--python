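"""Graph-based structural signatures of the wild-type residue environment.

Atoms around the mutated residue are typed with coarse physicochemical
pharmacophore labels (hydrophobic, aromatic, donor, acceptor, positive,
negative, sulfur, neutral; an atom may carry several). For every atom
pair in the environment and every label pair they realise, the
inter-atomic distance is binned on an ascending cutoff ladder and the
per-class counts are accumulated cumulatively along the ladder — a
distance-pattern summary of the local interaction graph ("cutoff
scanning"). The flattened count matrix is the signature block of the
feature vector.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from ppiddg import data as tables
from ppiddg.structure_io import Residue, ResidueRef, Structure

#: default environment sphere radius (A) around the mutated residue
DEFAULT_RADIUS = 10.0
#: default cutoff ladder (A): 1.0 to 10.0 in 0.5 steps
DEFAULT_CUTOFFS = tuple(np.arange(1.0, 10.0 + 1e-9, 0.5))

#: unordered pharmacophore label pairs, fixed order
PAIR_CLASSES = tuple(
    itertools.combinations_with_replacement(tables.PHARMACOPHORES, 2))


@dataclass
class LabeledAtom:
    coord: np.ndarray
    element: str
    labels: frozenset[str]


@dataclass
class AtomEnvironment:
    """Pharmacophore-typed heavy atoms within ``radius`` of ``center``."""

    center: np.ndarray
    atoms: list[LabeledAtom]
    radius: float


@dataclass
class StructuralSignature:
    """Cumulative pair-class x cutoff count matrix."""

    cutoffs: tuple[float, ...]
    counts: np.ndarray          # shape (len(PAIR_CLASSES), len(cutoffs)), int

    def flatten(self) -> np.ndarray:
        """Row-major flat vector, pair classes varying slowest."""
        return self.counts.reshape(-1).astype(float)

    @staticmethod
    def slot_names(cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS) -> list[str]:
        return [f"{a}-{b}@{c:g}" for (a, b) in PAIR_CLASSES for c in cutoffs]


def pharmacophore_labels(res: Residue, atom_name: str, element: str) -> frozenset[str]:
    """Pharmacophore labels of one atom, from the shipped residue tables.

    Unknown atoms fall back to 'neutral' with a warning; every atom gets
    at least one label.
    """
    resname = res.name
    known = resname in tables.RESIDUE_ATOMS and \
        atom_name in tables.RESIDUE_ATOMS[resname] + ["OXT"]
    if not known:
        warnings.warn(f"atom {resname}/{atom_name} not in pharmacophore "
                      "table; labeling neutral")
        return frozenset({"neutral"})
    labels: set[str] = set()
    if atom_name in tables.ring_atoms(resname):
        labels.add("aromatic")
    if atom_name == "N":
        if resname != "PRO":
            labels.add("donor")
    elif atom_name in ("O", "OXT"):
        labels.add("acceptor")
    if atom_name in tables.DONOR_ATOMS.get(resname, ()):
        labels.add("donor")
    if atom_name in tables.ACCEPTOR_ATOMS.get(resname, ()):
        labels.add("acceptor")
    if atom_name in tables.POSITIVE_ATOMS.get(resname, ()):
        labels.add("positive")
    if atom_name in tables.NEGATIVE_ATOMS.get(resname, ()):
        labels.add("negative")
    if atom_name in tables.SULFUR_ATOMS.get(resname, ()):
        labels.add("sulfur")
    # side-chain / CA carbons not otherwise typed are hydrophobic
    if element == "C" and atom_name not in ("C",) and not labels:
        labels.add("hydrophobic")
    if atom_name in tables.ring_atoms(resname) and element == "C":
        labels.add("hydrophobic")
    if not labels:
        labels.add("neutral")
    return frozenset(labels)


def assign_pharmacophores(s: Structure,
                          atoms: list[tuple[Residue, str]] | None = None
                          ) -> list[tuple[Residue, str, frozenset[str]]]:
    """Label atoms of ``s`` (all heavy atoms, or the given subset)."""
    out = []
    if atoms is None:
        for _, res, atom in s.heavy_atoms():
            out.append((res, atom.name, pharmacophore_labels(res, atom.name,
                                                             atom.element)))
    else:
        for res, name in atoms:
            atom = res.atom(name)
            out.append((res, name, pharmacophore_labels(res, name, atom.element)))
    return out


def extract_environment(s: Structure, r: ResidueRef,
                        radius: float = DEFAULT_RADIUS) -> AtomEnvironment:
    """All heavy atoms within ``radius`` of the mutated residue's center.

    Atoms from every chain are eligible, including those of the residue
    itself; an empty sphere is a valid (empty) environment.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = s.get_residue(r).center()
    atoms = []
    for _, res, atom in s.heavy_atoms():
        if np.linalg.norm(atom.coord - center) <= radius:
            labels = pharmacophore_labels(res, atom.name, atom.element)
            atoms.append(LabeledAtom(atom.coord.copy(), atom.element, labels))
    return AtomEnvironment(center=center, atoms=atoms, radius=radius)


def cutoff_scan_signature(env: AtomEnvironment,
                          cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
                          ) -> StructuralSignature:
    """Cumulative distance-pattern counts over pharmacophore pair classes.

    Each unordered atom pair contributes, for every unordered label pair
    it realises, one count at the smallest cutoff >= its distance; counts
    are then cumulated along the ladder. Pairs beyond the largest cutoff
    are dropped.
    """
    cutoffs = tuple(float(c) for c in cutoffs)
    if len(cutoffs) < 1 or any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly ascending and non-empty")
    pair_index = {p: i for i, p in enumerate(PAIR_CLASSES)}
    counts = np.zeros((len(PAIR_CLASSES), len(cutoffs)), dtype=np.int64)
    n = len(env.atoms)
    if n >= 2:
        coords = np.array([a.coord for a in env.atoms])
        dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        ladder = np.asarray(cutoffs)
        for i in range(n):
            for j in range(i + 1, n):
                d = dmat[i, j]
                if d > ladder[-1]:
                    continue
                k = int(np.searchsorted(ladder, d, side="left"))
                keys = {
                    (la, lb) if (la, lb) in pair_index else (lb, la)
                    for la in env.atoms[i].labels
                    for lb in env.atoms[j].labels
                }
                for key in keys:
                    counts[pair_index[key], k] += 1
    return StructuralSignature(cutoffs=cutoffs,
                               counts=np.cumsum(counts, axis=1))
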