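"""Feature families beyond the structural signature, and vector assembly.

Covers: glycine/proline mutation flags, evolutionary conservation scores
read from PSI-BLAST position-specific scoring matrices, pairwise
residue contact-potential lookups (AAindex matrix format), elastic
network model fluctuations of the mutated monomer, and an adapter for
externally computed energy terms. :func:`assemble_features` concatenates
all blocks into a named, deterministic feature vector.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ppiddg import data as tables
from ppiddg.interactions import ContactDelta, NetworkMetrics
from ppiddg.signatures import StructuralSignature
from ppiddg.structure_io import Structure

GLY, PRO = "G", "P"

VALID_AA = set(tables.AA_1TO3)


# ---------------------------------------------------------------------------
# mutation nature flags


def gly_pro_flags(wt_aa: str, mut_aa: str) -> tuple[int, int, int, int]:
    """(from_gly, to_gly, from_pro, to_pro) binary indicators.

    Glycine adds backbone flexibility and proline removes it, so
    mutations involving either can have outsized structural effects.
    """
    for aa in (wt_aa, mut_aa):
        if aa not in VALID_AA:
            raise ValueError(f"invalid amino acid code '{aa}'")
    return (int(wt_aa == GLY), int(mut_aa == GLY),
            int(wt_aa == PRO), int(mut_aa == PRO))


# ---------------------------------------------------------------------------
# PSSM


@dataclass
class PSSM:
    """Log-odds conservation scores from an iterated profile search."""

    query: str                   # query sequence, 1-based positions
    scores: np.ndarray           # (len(query), 20), PSI-BLAST column order

    def score(self, pos: int, aa: str) -> int:
        if not 1 <= pos <= len(self.query):
            raise IndexError(f"PSSM position {pos} out of range 1..{len(self.query)}")
        col = tables.PSSM_ORDER.index(aa)
        return int(self.scores[pos - 1, col])


def read_pssm(path: str | Path) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM file (the ``-out_ascii_pssm`` dialect).

    Only the 20 log-odds columns are read; the weighted-percentage block
    is ignored when present.
    """
    lines = Path(path).read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and "".join(toks[:20]) == tables.PSSM_ORDER:
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"{path}: no PSSM header row with the 20 standard "
                         "amino-acid columns")
    query, rows = [], []
    for lineno, line in enumerate(lines[header_idx + 1:], header_idx + 2):
        if not line.strip():
            break
        toks = line.split()
        if len(toks) < 22 or not toks[0].isdigit():
            raise ValueError(f"{path}:{lineno}: malformed PSSM row "
                             f"({len(toks) - 2 if len(toks) >= 2 else 0} score "
                             "columns, expected >= 20)")
        try:
            scores = [int(t) for t in toks[2:22]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer score") from exc
        query.append(toks[1])
        rows.append(scores)
    if not rows:
        raise ValueError(f"{path}: empty PSSM body")
    return PSSM(query="".join(query), scores=np.array(rows, dtype=int))


def evolutionary_scores(p: PSSM, pos: int, wt: str, mut: str
                        ) -> tuple[int, int, int]:
    """(wild-type score, mutant score, wt - mut) at one PSSM position.

    Fails loudly when the PSSM query letter at ``pos`` differs from the
    stated wild type — a misaligned numbering, not a value to guess at.
    """
    if not 1 <= pos <= len(p.query):
        raise IndexError(f"position {pos} outside PSSM of length {len(p.query)}")
    if p.query[pos - 1] != wt:
        raise ValueError(f"PSSM/structure misalignment at position {pos}: "
                         f"query has {p.query[pos - 1]}, mutation says {wt}")
    wt_score = p.score(pos, wt)
    mut_score = p.score(pos, mut)
    return wt_score, mut_score, wt_score - mut_score


# ---------------------------------------------------------------------------
# contact potentials (AAindex matrix format)


def read_aaindex_matrix(path: str | Path) -> dict[tuple[str, str], float]:
    """Parse one AAindex matrix entry (lower-triangular 'M rows =' layout)."""
    text = Path(path).read_text()
    m = re.search(r"^M rows = (\S+), cols = (\S+)\s*$", text, re.MULTILINE)
    if not m:
        raise ValueError(f"{path}: missing 'M rows = ..., cols = ...' line")
    rows_order, cols_order = m.group(1), m.group(2)
    body = text[m.end():].split("//")[0].strip().splitlines()
    table: dict[tuple[str, str], float] = {}
    for i, line in enumerate(body):
        vals = [float(v) for v in line.split()]
        if len(vals) not in (i + 1, len(cols_order)):
            raise ValueError(f"{path}: row {i + 1} has {len(vals)} values")
        for j, v in enumerate(vals):
            a, b = rows_order[i], cols_order[j]
            table[(a, b)] = v
            table[(b, a)] = v
    if len({k[0] for k in table}) != len(rows_order):
        raise ValueError(f"{path}: incomplete matrix body")
    return table


def default_contact_potentials() -> list[dict[tuple[str, str], float]]:
    """The three shipped contact-potential matrices.

    These are synthetic stand-in tables (built from hydrophobicity,
    charge-pair and volume-mismatch scales, see the files' headers), kept
    in AAindex matrix format so that user-supplied AAindex entries drop
    in unchanged via configuration.
    """
    pkg = importlib.resources.files("ppiddg.data")
    return [read_aaindex_matrix(pkg / f"contact_potential_synthetic_{i}.txt")
            for i in (1, 2, 3)]


def contact_potential_scores(wt: str, mut: str,
                             potentials: list[dict] | None = None
                             ) -> tuple[float, ...]:
    """Symmetric pair-potential lookups for the (wt, mut) residue pair."""
    for aa in (wt, mut):
        if aa not in VALID_AA:
            raise ValueError(f"invalid amino acid code '{aa}'")
    if potentials is None:
        potentials = default_contact_potentials()
    out = []
    for i, table in enumerate(potentials, 1):
        if (wt, mut) not in table:
            raise KeyError(f"contact potential table {i} has no cell "
                           f"({wt}, {mut})")
        out.append(float(table[(wt, mut)]))
    return tuple(out)


# ---------------------------------------------------------------------------
# elastic network model fluctuations


@dataclass
class FluctuationProfile:
    fluctuations: np.ndarray     # per CA residue, arbitrary units, > 0
    forcefield: str


def _hinsen_spring(d: float) -> float:
    # distance-dependent CA force constants, piecewise at 4 A
    if d < 4.0:
        return 8.6e2 * d - 2.39e3
    return 128e4 * d ** (-6)


def _enm_hessian(coords: np.ndarray, forcefield: str,
                 calpha_cutoff: float = 15.0) -> np.ndarray:
    n = len(coords)
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            dvec = coords[j] - coords[i]
            d = float(np.linalg.norm(dvec))
            if forcefield == "calpha":
                if d > calpha_cutoff:
                    continue
                k = _hinsen_spring(d)
            elif forcefield == "pfanm":
                k = 1.0 / d ** 2     # parameter-free: stiffness ~ 1/d^2
            else:
                raise ValueError(f"unknown force field '{forcefield}'")
            block = -k * np.outer(dvec, dvec) / d ** 2
            hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            hess[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
            hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            hess[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return hess


def enm_fluctuations(monomer: Structure, forcefield: str = "calpha",
                     zero_mode_rtol: float = 1e-8) -> FluctuationProfile:
    """Per-residue mean-square fluctuations of a CA elastic network.

    The CA-only Hessian uses either distance-dependent Hinsen spring
    constants ("calpha", 15 A pair cutoff) or parameter-free 1/d^2
    springs over all pairs ("pfanm"). Fluctuations are the per-residue
    trace of the Hessian pseudo-inverse, obtained by discarding exactly
    the six rigid-body modes; more than six near-zero modes means the
    geometry is degenerate and raises.
    """
    coords = np.array([res.atom("CA").coord
                       for _, res in monomer.iter_residues()
                       if res.atom("CA") is not None])
    if len(coords) < 4:
        raise ValueError("elastic network needs at least 4 CA atoms")
    span = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(span, tol=1e-6) < 3:
        raise ValueError("degenerate (planar or collinear) CA geometry")
    hess = _enm_hessian(coords, forcefield)
    evals, evecs = np.linalg.eigh(hess)
    tol = zero_mode_rtol * evals[-1]
    n_zero = int(np.sum(np.abs(evals) < tol))
    if n_zero != 6:
        raise ValueError(f"expected 6 rigid-body modes, found {n_zero} "
                         "near-zero eigenvalues")
    inv = np.zeros_like(evals)
    inv[6:] = 1.0 / evals[6:]
    # order eigenvalues ascending: first 6 are the rigid modes
    contrib = (evecs ** 2) @ inv
    fluct = contrib.reshape(-1, 3).sum(axis=1)
    return FluctuationProfile(fluctuations=fluct, forcefield=forcefield)


def monomer_view(s: Structure, chain_id: str) -> Structure:
    """Single-chain copy of ``s`` (the monomer carrying the mutation)."""
    return Structure(s.id + "_" + chain_id, [s.chain(chain_id).copy()],
                     s.source_format)


# ---------------------------------------------------------------------------
# energetic terms adapter


@dataclass
class EnergyTerms:
    interaction_energy: float    # kcal/mol, between the interacting chains
    folding_ddg: float           # kcal/mol, predicted stability change


class NullEnergyAdapter:
    """Explicit absent-marker source: no energetic terms available."""

    def terms(self) -> EnergyTerms | None:
        return None


class FoldXTableAdapter:
    """Reads interaction/folding energies from a FoldX-style table.

    Accepts tab-separated output with a header row; the columns holding
    the chain-chain interaction energy and the predicted folding free
    energy change are matched case-insensitively on
    'interaction energy' and 'total energy' / 'folding ddg'.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def terms(self) -> EnergyTerms | None:
        try:
            df = pd.read_csv(self.path, sep="\t")
        except Exception as exc:
            raise ValueError(f"cannot parse FoldX table {self.path}: {exc}")
        def find(patterns):
            for col in df.columns:
                low = col.strip().lower()
                if any(p in low for p in patterns):
                    return col
            raise ValueError(f"{self.path}: no column matching {patterns}")
        c_int = find(["interaction energy", "interaction_energy"])
        c_fold = find(["folding ddg", "folding_ddg", "total energy",
                       "total_energy"])
        if df.empty:
            raise ValueError(f"{self.path}: empty energy table")
        return EnergyTerms(float(df[c_int].iloc[0]), float(df[c_fold].iloc[0]))


def energetic_terms(source) -> EnergyTerms | None:
    """Energy terms from an adapter, or None (explicit absent-marker)."""
    return source.terms()


# ---------------------------------------------------------------------------
# feature vector assembly


@dataclass
class FeatureVector:
    """Named numeric predictor input with stable slot order."""

    names: tuple[str, ...]
    values: np.ndarray
    blocks: tuple[str, ...]      # block tags present, in assembly order

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


MANDATORY_BLOCKS = ("signature", "environment", "flags", "contact_delta",
                    "network")


def assemble_features(
    signature: StructuralSignature,
    environment: dict,
    flags: tuple[int, int, int, int],
    contact_delta: ContactDelta,
    network: NetworkMetrics,
    evolution: tuple[int, int, int] | None = None,
    potentials: tuple[float, ...] | None = None,
    fluctuation: dict[str, float] | None = None,
    energy: EnergyTerms | None = None,
) -> FeatureVector:
    """Concatenate feature blocks into one named vector.

    The five mandatory blocks must be present; optional blocks
    (evolution, potentials, fluctuation, energy) are either fully
    present or omitted from the vector — never silently zero-filled.
    The undefined-phi sentinel is encoded as (phi=0, phi_defined=0).
    """
    for name, val in (("signature", signature), ("environment", environment),
                      ("flags", flags), ("contact_delta", contact_delta),
                      ("network", network)):
        if val is None:
            raise ValueError(f"mandatory feature block '{name}' is missing")

    names: list[str] = []
    values: list[float] = []
    blocks: list[str] = []

    names += [f"sig:{n}" for n in
              StructuralSignature.slot_names(signature.cutoffs)]
    values += list(signature.flatten())
    blocks.append("signature")

    phi = environment["phi"]
    phi_defined = 0.0 if (phi is None or np.isnan(phi)) else 1.0
    names += ["env:rsa", "env:phi", "env:phi_defined", "env:depth"]
    values += [float(environment["rsa"]), float(phi if phi_defined else 0.0),
               phi_defined, float(environment["depth"])]
    comp = np.asarray(environment["aa_composition"], dtype=float)
    names += [f"env:aac_{a}" for a in tables.ALPHABET]
    values += list(comp)
    blocks.append("environment")

    names += ["flag:from_gly", "flag:to_gly", "flag:from_pro", "flag:to_pro"]
    values += [float(f) for f in flags]
    blocks.append("flags")

    names += ["cdelta:covalent", "cdelta:vdw", "cdelta:aromatic", "cdelta:hbond"]
    values += [float(v) for v in contact_delta.as_tuple()]
    blocks.append("contact_delta")

    net = network.as_dict()
    for key in ("mean_closeness", "central_point_dominance",
                "graph_center_size", "n_nodes", "n_edges"):
        names.append(f"net:{key}")
        values.append(net[key])
    blocks.append("network")

    if evolution is not None:
        names += ["evo:wt_score", "evo:mut_score", "evo:diff"]
        values += [float(v) for v in evolution]
        blocks.append("evolution")
    if potentials is not None:
        names += [f"pot:table{i}" for i in range(1, len(potentials) + 1)]
        values += [float(v) for v in potentials]
        blocks.append("potentials")
    if fluctuation is not None:
        for key in ("calpha_site", "calpha_mean", "pfanm_site", "pfanm_mean"):
            names.append(f"enm:{key}")
            values.append(float(fluctuation[key]))
        blocks.append("fluctuation")
    if energy is not None:
        names += ["energy:interaction_energy", "energy:folding_ddg"]
        values += [energy.interaction_energy, energy.folding_ddg]
        blocks.append("energy")

    return FeatureVector(names=tuple(names),
                         values=np.array(values, dtype=float),
                         blocks=tuple(blocks))


def feature_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack identically-shaped feature vectors into a DataFrame."""
    if not vectors:
        raise ValueError("no feature vectors")
    schema = vectors[0].names
    for v in vectors[1:]:
        if v.names != schema:
            raise ValueError("feature vectors have differing slot schemas")
    return pd.DataFrame([v.values for v in vectors], columns=list(schema))
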