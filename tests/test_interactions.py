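"""Contact typing, interface detection, network metrics and mutation grafts."""

import networkx as nx
import numpy as np
import pytest

from ppiddg import data as tables
from ppiddg import interactions as ia
from ppiddg import structure_io as sio
from ppiddg._templates import build_side_chain


def _residue(name, atom_specs, number=1):
    return sio.Residue(name, number, "", [
        sio.Atom(n, e, np.array(xyz, dtype=float)) for n, e, xyz in atom_specs])


def _two_chain(res_a, res_b):
    return sio.Structure("t", [sio.Chain("A", [res_a]), sio.Chain("B", [res_b])])


def _phe_pair(offset):
    """Two single-PHE chains; chain B translated by ``offset``."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = np.array([2.0, 1.4, 0.0])
    sc = build_side_chain("PHE", n, ca, c)
    atoms = [("N", "N", n), ("CA", "C", ca), ("C", "C", c),
             ("O", "O", c + np.array([1.1, 0.5, 0.0]))]
    atoms += [(k, k[0], v) for k, v in sc.items()]
    res_a = _residue("PHE", atoms)
    res_b = _residue("PHE", [(nm, el, np.asarray(xyz) + offset)
                             for nm, el, xyz in atoms])
    return _two_chain(res_a, res_b)


class TestDetectContacts:
    def test_two_carbons_at_bond_distance_covalent(self):
        res = _residue("ALA", [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))])
        s = sio.Structure("t", [sio.Chain("A", [res])])
        kinds = {c.kind for c in ia.detect_contacts(s)}
        # 1.5 <= 0.77 + 0.77 + 0.4
        assert kinds == {"covalent"}

    def test_backbone_nh_to_carbonyl_hbond(self):
        res_a = _residue("ALA", [("N", "N", (0, 0, 0)), ("CA", "C", (1.45, 0, 0))])
        res_b = _residue("ALA", [("O", "O", (0, 0, 2.9)), ("C", "C", (1.2, 0, 3.4))])
        s = _two_chain(res_a, res_b)
        hbonds = [c for c in ia.detect_contacts(s) if c.kind == "hbond"]
        assert len(hbonds) == 1
        assert hbonds[0].distance == pytest.approx(2.9)

    def test_far_atoms_no_contact(self):
        res_a = _residue("ALA", [("N", "N", (0, 0, 0))])
        res_b = _residue("ALA", [("O", "O", (0, 0, 12.0))])
        assert ia.detect_contacts(_two_chain(res_a, res_b)) == []

    def test_ring_stacking_detected(self):
        s = _phe_pair(np.array([0.0, 0.0, 4.0]))
        aro = [c for c in ia.detect_contacts(s) if c.kind == "aromatic"]
        assert len(aro) == 36  # 6 x 6 cross-ring atom pairs

    def test_symmetric_and_deterministic(self, toy_complex):
        c1 = ia.detect_contacts(toy_complex)
        c2 = ia.detect_contacts(toy_complex)
        assert c1 == c2
        for c in c1:
            assert c.distance > 0


class TestInterface:
    @pytest.mark.parametrize("gap,expect_nonempty", [(4.0, True), (6.0, False)])
    def test_matches_brute_force_on_toys(self, gap, expect_nonempty):
        s = sio.make_toy_complex(5, gap, 42)
        got = ia.interface_residues(s)
        # brute-force oracle over all inter-chain heavy-atom pairs
        expected = set()
        for ca, ra, aa in s.heavy_atoms():
            for cb, rb, ab in s.heavy_atoms():
                if ca.id >= cb.id:
                    continue
                if np.linalg.norm(aa.coord - ab.coord) <= 5.0:
                    expected.add((ca.id, ra.number, ra.icode))
                    expected.add((cb.id, rb.number, rb.icode))
        if expect_nonempty:
            assert got[("A", "B")] == expected
        else:
            assert got == {} and expected == set()

    def test_boundary_is_inclusive_at_exactly_5A(self):
        res_a = _residue("ALA", [("N", "N", (0.0, 0.0, 0.0))])
        res_b = _residue("ALA", [("N", "N", (0.0, 0.0, 5.0))])
        got = ia.interface_residues(_two_chain(res_a, res_b))
        assert got == {("A", "B"): {("A", 1, ""), ("B", 1, "")}}

    def test_monotone_in_cutoff(self, toy_complex):
        small = ia.interface_residues(toy_complex, 4.0).get(("A", "B"), set())
        large = ia.interface_residues(toy_complex, 6.5)[("A", "B")]
        assert small <= large

    def test_single_chain_raises(self):
        s = sio.Structure("t", [sio.Chain("A", [
            _residue("ALA", [("N", "N", (0, 0, 0))])])])
        with pytest.raises(ValueError, match="interface"):
            ia.interface_residues(s)


class TestClosestInterface:
    def test_two_chain_trivial(self, toy_complex):
        assert ia.closest_interface(toy_complex, sio.ResidueRef("A", 3)) == ("A", "B")

    def test_three_chain_picks_adjacent_pair(self):
        res_a = _residue("ALA", [("N", "N", (0, 0, 0)), ("CA", "C", (1.4, 0, 0))])
        res_b = _residue("ALA", [("N", "N", (0, 4.5, 0))], number=1)
        res_c = _residue("ALA", [("N", "N", (0, -4.9, 0))], number=1)
        s = sio.Structure("t", [sio.Chain("A", [res_a]),
                                sio.Chain("B", [res_b]),
                                sio.Chain("C", [res_c])])
        assert ia.closest_interface(s, sio.ResidueRef("A", 1)) == ("A", "B")

    def test_symmetric_tie_takes_lexicographic_pair(self):
        res_a = _residue("ALA", [("N", "N", (0, 0, 0))])
        res_b = _residue("ALA", [("N", "N", (0, 4.5, 0))])
        res_c = _residue("ALA", [("N", "N", (0, -4.5, 0))])
        s = sio.Structure("t", [sio.Chain("A", [res_a]),
                                sio.Chain("B", [res_b]),
                                sio.Chain("C", [res_c])])
        assert ia.closest_interface(s, sio.ResidueRef("A", 1)) == ("A", "B")


class TestNetworkMetrics:
    def _metrics(self, g):
        return ia.network_metrics(ia.ContactNetwork(g, ("A", "B")))

    def test_single_node(self):
        g = nx.Graph()
        g.add_node(0)
        m = self._metrics(g)
        assert (m.mean_closeness, m.central_point_dominance,
                m.graph_center_size) == (0.0, 0.0, 1)

    def test_path_of_three(self):
        m = self._metrics(nx.path_graph(3))
        # closeness: ends 2/3, middle 1; cpd = ((1-0)+(1-1)+(1-0))/2 = 1
        assert m.mean_closeness == pytest.approx((2 / 3 + 1.0 + 2 / 3) / 3)
        assert m.central_point_dominance == pytest.approx(1.0)
        assert m.graph_center_size == 1

    @pytest.mark.parametrize("n_leaves", [3, 5])
    def test_star_dominance_is_one(self, n_leaves):
        m = self._metrics(nx.star_graph(n_leaves))
        assert m.central_point_dominance == pytest.approx(1.0)
        assert m.graph_center_size == 1

    def test_cycle_and_complete_are_uniform(self):
        for g, closeness in ((nx.cycle_graph(4), 3 / 4),
                             (nx.complete_graph(5), 1.0)):
            m = self._metrics(g)
            assert m.mean_closeness == pytest.approx(closeness)
            assert m.central_point_dominance == pytest.approx(0.0)
            assert m.graph_center_size == g.number_of_nodes()

    def test_metrics_use_largest_component(self):
        g = nx.path_graph(4)
        g.add_node("isolated")
        m = self._metrics(g)
        assert m.n_nodes == 4


class TestMutate:
    def test_identity_mutation_is_exact_copy(self, toy_complex):
        m = ia.mutate_residue(toy_complex, sio.ResidueRef("A", 2), "F")
        for (_, _, a), (_, _, b) in zip(toy_complex.heavy_atoms(),
                                        m.heavy_atoms()):
            assert np.array_equal(a.coord, b.coord)

    def test_to_glycine_strips_side_chain(self, toy_complex):
        m = ia.mutate_residue(toy_complex, sio.ResidueRef("A", 2), "G")
        res = m.get_residue(sio.ResidueRef("A", 2))
        assert {a.name for a in res.atoms} == {"N", "CA", "C", "O"}

    def test_to_tryptophan_has_template_atom_count(self, poly_ala_complex):
        m = ia.mutate_residue(poly_ala_complex, sio.ResidueRef("A", 3), "W")
        res = m.get_residue(sio.ResidueRef("A", 3))
        assert len(res.atoms) == len(tables.RESIDUE_ATOMS["TRP"])

    def test_from_glycine_builds_cb(self, toy_complex):
        g = ia.mutate_residue(toy_complex, sio.ResidueRef("A", 4), "G")
        back = ia.mutate_residue(g, sio.ResidueRef("A", 4), "V")
        res = back.get_residue(sio.ResidueRef("A", 4))
        assert res.atom("CB") is not None
        assert {a.name for a in res.atoms} == set(tables.RESIDUE_ATOMS["VAL"])

    def test_backbone_untouched(self, toy_complex):
        ref = sio.ResidueRef("A", 2)
        m = ia.mutate_residue(toy_complex, ref, "K")
        wt_res = toy_complex.get_residue(ref)
        mut_res = m.get_residue(ref)
        for name in ("N", "CA", "C", "O"):
            assert np.array_equal(wt_res.atom(name).coord,
                                  mut_res.atom(name).coord)

    def test_invalid_code_rejected(self, toy_complex):
        with pytest.raises(ValueError):
            ia.mutate_residue(toy_complex, sio.ResidueRef("A", 2), "Z")


class TestContactDelta:
    def test_identity_is_zero(self, toy_complex):
        d = ia.contact_delta(toy_complex, sio.ResidueRef("A", 2), "F")
        assert d.as_tuple() == (0, 0, 0, 0)

    def test_removing_stacked_ring_loses_aromatic_contacts(self):
        s = _phe_pair(np.array([0.0, 0.0, 4.0]))
        d = ia.contact_delta(s, sio.ResidueRef("A", 1), "A")
        assert d.aromatic >= 1

    def test_isolated_site_changes_only_covalent_counts(self):
        # two single-residue chains 30 A apart: no inter-residue contacts
        res_a = _residue("ALA", [("N", "N", (0, 0, 0)),
                                 ("CA", "C", (1.458, 0, 0)),
                                 ("C", "C", (2.0, 1.4, 0)),
                                 ("O", "O", (3.2, 1.5, 0)),
                                 ("CB", "C", (1.9, -0.8, 1.2))])
        res_b = _residue("ALA", [("N", "N", (0, 0, 30.0))])
        s = _two_chain(res_a, res_b)
        d = ia.contact_delta(s, sio.ResidueRef("A", 1), "W")
        assert d.covalent != 0
        assert (d.vdw, d.aromatic, d.hbond) == (0, 0, 0)
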