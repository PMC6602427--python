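"""Structure model, I/O and residue-environment descriptors.

Structures are read with gemmi (PDB v3.3 and mmCIF) into a small mutable
chain/residue/atom model. Waters and hetero compounds are dropped on
read; at most one altloc conformer per atom is kept (highest occupancy,
ties broken toward altloc 'A'). Descriptors computed here — relative
solvent accessibility, backbone phi torsion, residue depth and chain
amino-acid composition — form the wild-type environment block of the
feature vector.

Solvent-accessible surface areas use an in-house Shrake-Rupley
implementation (960 golden-spiral points, 1.4 A probe, heavy atoms only)
so that depth and RSA share one consistent surface definition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from ppiddg import data as tables
from ppiddg._geometry import dihedral, ideal_cb, place_atom
from ppiddg._templates import build_side_chain

PROBE_RADIUS = 1.4
SASA_POINTS = 960

#: sentinel for undefined torsion angles (chain starts, missing atoms)
UNDEFINED_ANGLE = float("nan")


class StructureFormatError(ValueError):
    """File could not be parsed as PDB or mmCIF."""


class EmptyStructureError(ValueError):
    """Parsed file contains no polymer atoms."""


class ResidueResolutionError(KeyError):
    """A ResidueRef does not resolve to exactly one residue."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy(),
                    self.occupancy, self.altloc)


@dataclass
class Residue:
    name: str                       # three-letter code
    number: int                     # author numbering, 1-based
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def aa(self) -> str:
        """One-letter code ('X' for non-standard residues)."""
        return tables.AA_3TO1.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def center(self) -> np.ndarray:
        """Geometric center of heavy atoms."""
        return np.mean([a.coord for a in self.heavy_atoms()], axis=0)

    def copy(self) -> "Residue":
        return Residue(self.name, self.number, self.icode,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclass(frozen=True)
class ResidueRef:
    """Reference to one residue: chain id, author number, optional icode.

    ``aa`` optionally asserts the expected wild-type one-letter code; when
    given, resolution fails loudly on a mismatch instead of silently
    pointing at the wrong residue.
    """

    chain_id: str
    res_number: int
    icode: str = ""
    aa: str | None = None


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "pdb"

    # -- access ---------------------------------------------------------
    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise ResidueResolutionError(f"no chain '{chain_id}' in structure {self.id}")

    def get_residue(self, ref: ResidueRef) -> Residue:
        chain = self.chain(ref.chain_id)
        hits = [r for r in chain.residues
                if r.number == ref.res_number and r.icode == (ref.icode or "")]
        if len(hits) != 1:
            raise ResidueResolutionError(
                f"residue {ref.chain_id}/{ref.res_number}{ref.icode} resolves to "
                f"{len(hits)} residues in structure {self.id}")
        res = hits[0]
        if ref.aa is not None and res.aa != ref.aa:
            raise ResidueResolutionError(
                f"wild-type mismatch at {ref.chain_id}/{ref.res_number}: "
                f"structure has {res.aa}, mutation specifies {ref.aa}")
        return res

    def iter_residues(self):
        for chain in self.chains:
            for res in chain.residues:
                yield chain, res

    def heavy_atoms(self):
        """Yield (chain, residue, atom) for every non-hydrogen atom."""
        for chain, res in self.iter_residues():
            for atom in res.atoms:
                if atom.element != "H":
                    yield chain, res, atom

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for _, _, a in self.heavy_atoms()], dtype=float)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    def copy(self) -> "Structure":
        return Structure(self.id, [c.copy() for c in self.chains], self.source_format)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body transformed copy (coords @ R.T + t)."""
        out = self.copy()
        for _, res in out.iter_residues():
            for atom in res.atoms:
                atom.coord = rotation @ atom.coord + translation
        return out


# ---------------------------------------------------------------------------
# reading / writing


def _dedup_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> altloc 'A'."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in raw_atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        group.sort(key=lambda a: (-a.occupancy, a.altloc or "A"))
        out.append(group[0])
    return out


def read_structure(path_or_id: str | Path) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    ``path_or_id`` may be a file path or a bare accession code, in which
    case a local file named ``<code>.pdb`` / ``<code>.cif`` / ``<code>.ent``
    must exist beside the working directory (no network access). Only the
    first model is read; waters and hetero compounds are dropped.
    """
    path = Path(path_or_id)
    if not path.exists():
        for ext in (".pdb", ".cif", ".ent"):
            cand = Path(str(path_or_id) + ext)
            if cand.exists():
                path = cand
                break
        else:
            raise FileNotFoundError(
                f"no local structure file found for '{path_or_id}'")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse '{path}': {exc}") from exc
    st.setup_entities()
    fmt = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"

    out = Structure(id=st.name or path.stem, source_format=fmt)
    if len(st) == 0:
        raise EmptyStructureError(f"'{path}' contains no models")
    model = st[0]
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            if gres.is_water() or gres.name not in tables.AA_3TO1:
                continue
            raw = [
                Atom(name=ga.name, element=ga.element.name.upper(),
                     coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                     occupancy=ga.occ, altloc=ga.altloc or "")
                for ga in gres
            ]
            res = Residue(name=gres.name, number=gres.seqid.num,
                          icode=(gres.seqid.icode or "").strip(),
                          atoms=_dedup_altlocs(raw))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        raise EmptyStructureError(f"'{path}' contains no standard polymer residues")
    return out


def write_pdb(s: Structure, path: str | Path) -> None:
    """Minimal PDB v3.3 writer (fixtures and round-trips)."""
    lines = []
    serial = 1
    for chain in s.chains:
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.name:>3s} {chain.id:1s}"
                    f"{res.number:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}")
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].name:>3s} "
                     f"{chain.id:1s}{chain.residues[-1].number:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# solvent accessibility


def _sphere_points(n: int) -> np.ndarray:
    """Golden-spiral quasi-uniform points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _vdw_radius(element: str, atom_name: str = "?") -> float:
    try:
        return tables.VDW_RADII[element]
    except KeyError:
        warnings.warn(f"unknown element '{element}' for atom {atom_name}; "
                      "using 1.80 A radius")
        return 1.80


def atom_sasa(s: Structure, n_points: int = SASA_POINTS,
              probe: float = PROBE_RADIUS) -> np.ndarray:
    """Shrake-Rupley per-atom SASA (A^2) over all heavy atoms of ``s``.

    Order matches :meth:`Structure.heavy_atoms`.
    """
    atoms = list(s.heavy_atoms())
    coords = np.array([a.coord for _, _, a in atoms])
    radii = np.array([_vdw_radius(a.element, a.name) + probe for _, _, a in atoms])
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    out = np.zeros(len(atoms))
    rmax = radii.max()
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                 if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(pts - coords[j], axis=1)
            exposed &= d >= radii[j]
            if not exposed.any():
                break
        out[i] = 4.0 * math.pi * radii[i] ** 2 * exposed.sum() / n_points
    return out


def residue_sasa(s: Structure) -> dict[tuple[str, int, str], float]:
    """Total SASA per residue, keyed by (chain_id, number, icode)."""
    per_atom = atom_sasa(s)
    out: dict[tuple[str, int, str], float] = {}
    for (chain, res, _), a in zip(s.heavy_atoms(), per_atom):
        key = (chain.id, res.number, res.icode)
        out[key] = out.get(key, 0.0) + a
    return out


def relative_solvent_accessibility(s: Structure, r: ResidueRef) -> float:
    """Residue SASA in the full complex over its theoretical maximum ASA."""
    res = s.get_residue(r)
    if res.aa == "X":
        raise ValueError(f"cannot normalise SASA for non-standard residue "
                         f"{res.name} at {r.chain_id}/{r.res_number}")
    total = residue_sasa(s)[(r.chain_id, r.res_number, r.icode or "")]
    return total / tables.MAX_ASA[res.aa]


# ---------------------------------------------------------------------------
# torsions and depth


def phi_torsion(s: Structure, r: ResidueRef) -> float:
    """Backbone phi dihedral C(i-1)-N-CA-C in degrees.

    NaN (with a warning for missing atoms) when the residue is first in
    its chain or backbone atoms are absent.
    """
    chain = s.chain(r.chain_id)
    res = s.get_residue(r)
    idx = chain.residues.index(res)
    if idx == 0:
        return UNDEFINED_ANGLE
    prev = chain.residues[idx - 1]
    c_prev = prev.atom("C")
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if any(a is None for a in (c_prev, n, ca, c)):
        warnings.warn(f"missing backbone atom around {r.chain_id}/{r.res_number}; "
                      "phi undefined")
        return UNDEFINED_ANGLE
    return dihedral(c_prev.coord, n.coord, ca.coord, c.coord)


def residue_depth(s: Structure, r: ResidueRef) -> float:
    """Mean distance (A) from the residue's heavy atoms to the surface.

    The surface is the set of heavy atoms with nonzero Shrake-Rupley
    SASA; depth is the mean nearest-surface-atom-center distance, so a
    solvent-exposed residue has depth near zero.
    """
    atoms = list(s.heavy_atoms())
    if len(atoms) < 2:
        raise ValueError("residue depth requires at least two residues")
    sasa = atom_sasa(s)
    surface = np.array([a.coord for (_, _, a), sa in zip(atoms, sasa) if sa > 0.0])
    if surface.size == 0:
        raise ValueError("degenerate structure: no solvent-exposed atoms")
    res = s.get_residue(r)
    tree = cKDTree(surface)
    dists, _ = tree.query(np.array([a.coord for a in res.heavy_atoms()]))
    return float(np.mean(dists))


def aa_composition(sequence: str) -> np.ndarray:
    """Amino-acid frequency 20-vector, alphabetical by one-letter code.

    'X' placeholders are allowed but excluded from the denominator.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set(tables.ALPHABET) - {"X"}
    if bad:
        raise ValueError(f"invalid residue letters: {sorted(bad)}")
    counted = [c for c in seq if c != "X"]
    if not counted:
        raise ValueError("sequence contains only 'X'")
    vec = np.array([counted.count(a) for a in tables.ALPHABET], dtype=float)
    return vec / len(counted)


# ---------------------------------------------------------------------------
# synthetic fixtures


_BB = {"n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
       "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
       "ang_ca_c_o": 120.5}


def _build_chain(chain_id: str, n_res: int, sequence: str | None,
                 phi: float, psi: float, rng: np.random.Generator) -> Chain:
    seq = (sequence or "A" * n_res).upper()
    chain = Chain(id=chain_id)
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BB["n_ca"], 0.0, 0.0])
    c = place_atom(np.array([-1.0, 1.0, 0.0]), n, ca,
                   _BB["ca_c"], _BB["ang_n_ca_c"], 150.0)
    for i in range(n_res):
        resname = tables.AA_1TO3[seq[i]]
        res = Residue(name=resname, number=i + 1)
        o = place_atom(n, ca, c, _BB["c_o"], _BB["ang_ca_c_o"], psi - 180.0)
        res.atoms = [Atom("N", "N", n), Atom("CA", "C", ca),
                     Atom("C", "C", c), Atom("O", "O", o)]
        for name, xyz in build_side_chain(resname, n, ca, c).items():
            res.atoms.append(Atom(name, name[0], xyz))
        chain.residues.append(res)
        if i + 1 < n_res:
            n_next = place_atom(n, ca, c, _BB["c_n"], _BB["ang_ca_c_n"], psi)
            ca_next = place_atom(ca, c, n_next, _BB["n_ca"], _BB["ang_c_n_ca"], 180.0)
            c_next = place_atom(c, n_next, ca_next, _BB["ca_c"],
                                _BB["ang_n_ca_c"], phi)
            n, ca, c = n_next, ca_next, c_next
    # small deterministic jitter breaks exact symmetry between fixtures
    for res in chain.residues:
        for atom in res.atoms:
            atom.coord = atom.coord + rng.normal(scale=0.02, size=3)
    return chain


def _min_interchain_distance(a: Chain, b: Chain) -> float:
    ca = np.array([at.coord for r in a.residues for at in r.atoms if at.element != "H"])
    cb = np.array([at.coord for r in b.residues for at in r.atoms if at.element != "H"])
    return float(cKDTree(ca).query(cb)[0].min())


def make_toy_complex(n_res_per_chain: int, gap: float, seed: int,
                     sequence_a: str | None = None,
                     sequence_b: str | None = None) -> Structure:
    """Deterministic two-chain toy complex for tests and demonstrations.

    Two extended poly-alanine chains (optionally with per-residue
    substitutions given as full one-letter sequences) are placed so that
    the minimal inter-chain heavy-atom distance equals ``gap`` within
    0.1 A. Identical arguments give bit-identical coordinates.
    """
    if n_res_per_chain < 1:
        raise ValueError("n_res_per_chain must be >= 1")
    if gap <= 0:
        raise ValueError("gap must be positive")
    rng = np.random.default_rng(seed)
    chain_a = _build_chain("A", n_res_per_chain, sequence_a, -120.0, 140.0, rng)
    chain_b = _build_chain("B", n_res_per_chain, sequence_b, -120.0, 140.0, rng)
    # separate along +y, then fix the point of closest approach onto `gap`
    coords_a = np.array([at.coord for r in chain_a.residues for at in r.atoms])
    span = coords_a[:, 1].max() - coords_a[:, 1].min()
    shift = np.array([0.0, span + gap + 5.0, 0.0])
    for res in chain_b.residues:
        for atom in res.atoms:
            atom.coord = atom.coord + shift
    for _ in range(80):
        d = _min_interchain_distance(chain_a, chain_b)
        err = gap - d
        if abs(err) < 0.01:
            break
        for res in chain_b.residues:
            for atom in res.atoms:
                atom.coord = atom.coord + np.array([0.0, err, 0.0])
    # snap the closest pair onto `gap` exactly (analytic y-shift)
    xa = np.array([at.coord for r in chain_a.residues for at in r.atoms])
    xb = np.array([at.coord for r in chain_b.residues for at in r.atoms])
    dmat = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmin(dmat), dmat.shape)
    dx, dy, dz = xb[j] - xa[i]
    if gap ** 2 > dx ** 2 + dz ** 2:
        t = np.sqrt(gap ** 2 - dx ** 2 - dz ** 2) - dy
        for res in chain_b.residues:
            for atom in res.atoms:
                atom.coord = atom.coord + np.array([0.0, t, 0.0])
    return Structure(id=f"toy{n_res_per_chain}", chains=[chain_a, chain_b])


def make_helix(n_res: int) -> Structure:
    """Single-chain ideal alpha-helical poly-alanine (phi=-57, psi=-47).

    No coordinate jitter: helices serve as exact-geometry fixtures.
    """
    exact = _build_chain("A", n_res, None, -57.0, -47.0, _ZeroRng())
    return Structure(id="helix", chains=[exact])


class _ZeroRng:
    """Stand-in RNG producing zero jitter (exact ideal geometry)."""

    def normal(self, scale: float = 1.0, size=None):
        return np.zeros(size) if size else 0.0
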