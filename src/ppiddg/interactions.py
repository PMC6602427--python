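"""Non-covalent contact typing, interface detection and network analysis.

Contacts are classified into the four classes the predictor consumes —
covalent, van der Waals, aromatic and hydrogen bond — with explicit
distance rules over shipped radii and donor/acceptor tables (heavy atoms
only, no angle terms, so the rules work on hydrogen-free crystal
structures). A residue belongs to an interface when any of its heavy
atoms lies within 5 A (inclusive) of another chain. The contact graph of
the interface closest to the mutated residue is summarised with
closeness centrality, Freeman central-point dominance and graph-center
size. Wild-type -> mutant contact-count differences come from a
deterministic idealised side-chain graft.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from ppiddg import data as tables
from ppiddg._geometry import ideal_cb
from ppiddg._templates import build_side_chain
from ppiddg.structure_io import (
    Atom,
    Residue,
    ResidueRef,
    Structure,
)

CONTACT_KINDS = ("covalent", "vdw", "aromatic", "hbond")

#: distance-rule parameters (A); all cutoffs inclusive
CONTACT_RULES = {
    "covalent_slack": 0.4,      # d <= r_cov(a) + r_cov(b) + slack
    "hbond_max": 3.9,           # donor..acceptor heavy-atom distance
    "aromatic_centroid_max": 5.0,
    "vdw_slack": 0.5,           # d <= r_vdw(a) + r_vdw(b) + slack
}

INTERFACE_CUTOFF = 5.0


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    res_number: int
    icode: str
    res_name: str
    atom_name: str

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_number, self.icode)


@dataclass(frozen=True)
class Contact:
    atom_a: AtomRef
    atom_b: AtomRef
    kind: str
    distance: float


@dataclass
class ContactNetwork:
    """Residue-level contact graph of one chain-pair interface."""

    graph: nx.Graph
    interface_id: tuple[str, str]


@dataclass
class NetworkMetrics:
    mean_closeness: float
    central_point_dominance: float
    graph_center_size: int
    n_nodes: int
    n_edges: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_closeness": self.mean_closeness,
            "central_point_dominance": self.central_point_dominance,
            "graph_center_size": float(self.graph_center_size),
            "n_nodes": float(self.n_nodes),
            "n_edges": float(self.n_edges),
        }


@dataclass
class ContactDelta:
    """Wild-type minus mutant contact counts for the mutated residue."""

    covalent: int
    vdw: int
    aromatic: int
    hbond: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.covalent, self.vdw, self.aromatic, self.hbond)


# ---------------------------------------------------------------------------
# contact detection


def _cov_radius(element: str, ref: AtomRef) -> float:
    try:
        return tables.COVALENT_RADII[element]
    except KeyError:
        raise ValueError(f"unknown element '{element}' for atom "
                         f"{ref.chain_id}/{ref.res_number}/{ref.atom_name}")


def _is_donor(ref: AtomRef) -> bool:
    if ref.atom_name == "N" and ref.res_name != "PRO":
        return True
    return ref.atom_name in tables.DONOR_ATOMS.get(ref.res_name, ())


def _is_acceptor(ref: AtomRef) -> bool:
    if ref.atom_name in ("O", "OXT"):
        return True
    return ref.atom_name in tables.ACCEPTOR_ATOMS.get(ref.res_name, ())


def _atom_table(s: Structure):
    refs, coords, elements = [], [], []
    for chain, res, atom in s.heavy_atoms():
        refs.append(AtomRef(chain.id, res.number, res.icode, res.name, atom.name))
        coords.append(atom.coord)
        elements.append(atom.element)
    return refs, np.array(coords), elements


def detect_contacts(s: Structure, rules: dict | None = None) -> list[Contact]:
    """Classify heavy-atom pairs into the four contact classes.

    A pair may carry several kinds (e.g. hydrogen-bonded atoms inside the
    van der Waals envelope). Aromatic contacts link atoms of two rings
    whose centroids are at most 5 A apart.
    """
    rules = {**CONTACT_RULES, **(rules or {})}
    refs, coords, elements = _atom_table(s)
    if len(refs) == 0:
        raise ValueError("empty structure")
    contacts: list[Contact] = []

    max_r = max(
        2 * max(tables.COVALENT_RADII.values()) + rules["covalent_slack"],
        rules["hbond_max"],
        2 * max(tables.VDW_RADII.values()) + rules["vdw_slack"],
    )
    tree = cKDTree(coords)
    for i, j in sorted(tree.query_pairs(max_r)):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        a, b = refs[i], refs[j]
        cov_cut = (_cov_radius(elements[i], a) + _cov_radius(elements[j], b)
                   + rules["covalent_slack"])
        is_cov = d <= cov_cut
        if is_cov:
            contacts.append(Contact(a, b, "covalent", d))
        elif d <= (tables.VDW_RADII.get(elements[i], 1.8)
                   + tables.VDW_RADII.get(elements[j], 1.8) + rules["vdw_slack"]):
            contacts.append(Contact(a, b, "vdw", d))
        if d <= rules["hbond_max"] and not is_cov:
            if (_is_donor(a) and _is_acceptor(b)) or (_is_donor(b) and _is_acceptor(a)):
                contacts.append(Contact(a, b, "hbond", d))

    contacts.extend(_aromatic_contacts(s, rules["aromatic_centroid_max"]))
    return contacts


def _rings(s: Structure) -> list[tuple[list[AtomRef], np.ndarray]]:
    out = []
    for chain, res in s.iter_residues():
        for ring in tables.AROMATIC_RINGS.get(res.name, []):
            atoms = [(res.atom(n), n) for n in ring]
            if any(a is None for a, _ in atoms):
                continue
            refs = [AtomRef(chain.id, res.number, res.icode, res.name, n)
                    for _, n in atoms]
            centroid = np.mean([a.coord for a, _ in atoms], axis=0)
            out.append((refs, centroid))
    return out


def _aromatic_contacts(s: Structure, centroid_max: float) -> list[Contact]:
    rings = _rings(s)
    coords = {}
    for chain, res, atom in s.heavy_atoms():
        coords[AtomRef(chain.id, res.number, res.icode, res.name, atom.name)] = atom.coord
    contacts = []
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            refs_i, cen_i = rings[i]
            refs_j, cen_j = rings[j]
            # two rings of the same residue (tryptophan) are not a stack
            if refs_i[0].residue_key == refs_j[0].residue_key:
                continue
            if float(np.linalg.norm(cen_i - cen_j)) <= centroid_max:
                for a in refs_i:
                    for b in refs_j:
                        d = float(np.linalg.norm(coords[a] - coords[b]))
                        contacts.append(Contact(a, b, "aromatic", d))
    return contacts


# ---------------------------------------------------------------------------
# interfaces


def interface_residues(s: Structure, cutoff: float = INTERFACE_CUTOFF
                       ) -> dict[tuple[str, str], set[tuple[str, int, str]]]:
    """Interfacial residues per chain pair (5 A heavy-atom rule, inclusive).

    Returns ``{(chain_a, chain_b): {residue keys of both chains}}``,
    chain pairs in lexicographic order; pairs with no interfacial
    residue are omitted.
    """
    if len(s.chains) < 2:
        raise ValueError("no interface: structure has a single chain")
    per_chain = {}
    for chain in s.chains:
        refs, coords = [], []
        for res in chain.residues:
            for atom in res.heavy_atoms():
                refs.append((chain.id, res.number, res.icode))
                coords.append(atom.coord)
        per_chain[chain.id] = (refs, np.array(coords))
    out: dict[tuple[str, str], set] = {}
    ids = sorted(per_chain)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            refs_a, xa = per_chain[ids[i]]
            refs_b, xb = per_chain[ids[j]]
            d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
            close = d <= cutoff
            members = {refs_a[k] for k in np.nonzero(close.any(axis=1))[0]}
            members |= {refs_b[k] for k in np.nonzero(close.any(axis=0))[0]}
            if members:
                out[(ids[i], ids[j])] = members
    return out


def closest_interface(s: Structure, r: ResidueRef,
                      cutoff: float = INTERFACE_CUTOFF) -> tuple[str, str]:
    """Chain-pair interface nearest to the mutated residue.

    Distance is taken from the residue's geometric center to the
    midpoints of the closest inter-chain atom pairs of each interface;
    ties resolve to the lexicographically first chain pair.
    """
    interfaces = interface_residues(s, cutoff)
    if not interfaces:
        raise ValueError("no interface within cutoff")
    center = s.get_residue(r).center()
    best, best_d = None, np.inf
    for pair in sorted(interfaces):
        ca, cb = pair
        xa = np.array([a.coord for ch, res in s.iter_residues() if ch.id == ca
                       for a in res.heavy_atoms()])
        xb = np.array([a.coord for ch, res in s.iter_residues() if ch.id == cb
                       for a in res.heavy_atoms()])
        d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        midpoint = (xa[i] + xb[j]) / 2.0
        dist = float(np.linalg.norm(center - midpoint))
        if dist < best_d - 1e-12:
            best, best_d = pair, dist
    return best


def build_contact_network(s: Structure, interface: tuple[str, str],
                          cutoff: float = INTERFACE_CUTOFF,
                          contacts: list[Contact] | None = None) -> ContactNetwork:
    """Residue-level typed contact graph over one interface's residues."""
    members = interface_residues(s, cutoff).get(interface, set())
    graph = nx.Graph()
    graph.add_nodes_from(sorted(members))
    if contacts is None:
        contacts = detect_contacts(s)
    for c in contacts:
        ka, kb = c.atom_a.residue_key, c.atom_b.residue_key
        if ka == kb or ka not in members or kb not in members:
            continue
        if graph.has_edge(ka, kb):
            graph[ka][kb]["kinds"].append(c.kind)
        else:
            graph.add_edge(ka, kb, kinds=[c.kind])
    return ContactNetwork(graph=graph, interface_id=interface)


def network_metrics(net: ContactNetwork) -> NetworkMetrics:
    """Centrality summary of the largest connected component."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty contact network")
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)[0]))
    sub = g.subgraph(comp)
    n = sub.number_of_nodes()
    if n == 1:
        return NetworkMetrics(0.0, 0.0, 1, 1, 0)
    closeness = nx.closeness_centrality(sub)
    betweenness = nx.betweenness_centrality(sub, normalized=True)
    bmax = max(betweenness.values())
    cpd = sum(bmax - b for b in betweenness.values()) / (n - 1)
    center = nx.center(sub)
    return NetworkMetrics(
        mean_closeness=float(np.mean(list(closeness.values()))),
        central_point_dominance=float(cpd),
        graph_center_size=len(center),
        n_nodes=n,
        n_edges=sub.number_of_edges(),
    )


# ---------------------------------------------------------------------------
# mutant modelling and contact deltas


def mutate_residue(s: Structure, r: ResidueRef, mut_aa: str) -> Structure:
    """Graft an idealised ``mut_aa`` side chain onto the residue's backbone.

    The backbone (N, CA, C, O) is untouched; the replacement side chain
    uses ideal geometry in its most common rotamer, built on the
    N-CA-C(B) frame (a virtual CB is reconstructed when mutating away
    from glycine). Deterministic; an identity mutation returns an exact
    copy.
    """
    if mut_aa not in tables.AA_1TO3:
        raise ValueError(f"invalid mutant amino acid '{mut_aa}'")
    out = s.copy()
    res = out.get_residue(r)
    if res.aa == mut_aa:
        return out
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if any(a is None for a in (n, ca, c)):
        raise ValueError(f"residue {r.chain_id}/{r.res_number} lacks backbone "
                         "atoms needed for mutation")
    new_name = tables.AA_1TO3[mut_aa]
    backbone = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "OXT")]
    # keep the crystallographic CB orientation when the wild type has one
    wt_cb = res.atom("CB")
    side = build_side_chain(new_name, n.coord, ca.coord, c.coord,
                            cb=None if wt_cb is None else wt_cb.coord)
    res.name = new_name
    res.atoms = backbone
    for name, xyz in side.items():
        res.atoms.append(Atom(name, name[0], np.asarray(xyz, dtype=float).copy()))
    return out


def residue_contact_counts(contacts: list[Contact],
                           key: tuple[str, int, str]) -> dict[str, int]:
    """Per-kind counts of contacts touching one residue.

    Covalent counts include the residue's own bond network (so side-chain
    size is reflected); the non-covalent kinds count only contacts to
    OTHER residues — a residue isolated in space has zero of them.
    """
    counts = dict.fromkeys(CONTACT_KINDS, 0)
    for c in contacts:
        in_a = c.atom_a.residue_key == key
        in_b = c.atom_b.residue_key == key
        if not (in_a or in_b):
            continue
        if in_a and in_b and c.kind != "covalent":
            continue
        counts[c.kind] += 1
    return counts


def contact_delta(wt: Structure, r: ResidueRef, mut_aa: str) -> ContactDelta:
    """Wild-type minus mutant contact counts at the mutated residue."""
    key = (r.chain_id, r.res_number, r.icode or "")
    wt_counts = residue_contact_counts(detect_contacts(wt), key)
    mut = mutate_residue(wt, r, mut_aa)
    mut_counts = residue_contact_counts(detect_contacts(mut), key)
    return ContactDelta(*(wt_counts[k] - mut_counts[k] for k in CONTACT_KINDS))
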