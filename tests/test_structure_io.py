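"""Structure reading, SASA/RSA, torsions, depth and toy fixtures."""

import gemmi
import numpy as np
import pytest

from ppiddg import structure_io as sio
from ppiddg._geometry import random_rotation

from conftest import DATA_DIR


def _single_residue(name, atom_specs, chain="A", number=1):
    atoms = [sio.Atom(n, e, np.array(xyz, dtype=float))
             for n, e, xyz in atom_specs]
    return sio.Structure("t", [sio.Chain(chain, [sio.Residue(name, number,
                                                             "", atoms)])])


class TestReadWrite:
    def test_round_trip_preserves_atoms_and_coords(self, toy_complex, tmp_path):
        path = tmp_path / "toy.pdb"
        sio.write_pdb(toy_complex, path)
        back = sio.read_structure(path)
        assert back.n_atoms() == toy_complex.n_atoms()
        assert len(back.chains) == 2
        err = np.abs(back.heavy_coords() - toy_complex.heavy_coords()).max()
        assert err < 1e-3

    def test_pdb_and_mmcif_give_identical_structures(self, toy_complex, tmp_path):
        pdb_path = tmp_path / "x.pdb"
        sio.write_pdb(toy_complex, pdb_path)
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "x.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        s_pdb = sio.read_structure(pdb_path)
        s_cif = sio.read_structure(cif_path)
        assert s_cif.source_format == "mmcif"
        assert s_pdb.n_atoms() == s_cif.n_atoms()
        assert np.abs(s_pdb.heavy_coords() - s_cif.heavy_coords()).max() < 1e-3

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        pdb = (
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.60  0.00           N\n"
            "ATOM      2  N  BALA A   1       9.000   9.000   9.000  0.40  0.00           N\n"
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "END\n")
        path = tmp_path / "altloc.pdb"
        path.write_text(pdb)
        s = sio.read_structure(path)
        res = s.chains[0].residues[0]
        ns = [a for a in res.atoms if a.name == "N"]
        assert len(ns) == 1
        assert np.allclose(ns[0].coord, [0, 0, 0])

    def test_unparseable_and_missing_files(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("data_x\n_nonsense 1\n")
        with pytest.raises((sio.StructureFormatError, sio.EmptyStructureError)):
            sio.read_structure(bad)
        with pytest.raises(FileNotFoundError):
            sio.read_structure(tmp_path / "1XYZ")


class TestRSA:
    def test_isolated_glycine_fully_exposed(self):
        s = _single_residue("GLY", [("N", "N", (0, 0, 0)),
                                    ("CA", "C", (1.458, 0, 0)),
                                    ("C", "C", (2.0, 1.35, 0)),
                                    ("O", "O", (3.2, 1.45, 0))])
        assert sio.relative_solvent_accessibility(s, sio.ResidueRef("A", 1)) > 0.7

    def test_buried_residue_in_dense_shell(self):
        # glycine at the center of two occluding spherical atom shells
        rng = np.random.default_rng(1)
        center = _single_residue("GLY", [("N", "N", (0, 0, 0)),
                                         ("CA", "C", (1.0, 0, 0)),
                                         ("C", "C", (0, 1.0, 0)),
                                         ("O", "O", (0, 0, 1.0))])
        shell_res = sio.Residue("ALA", 1, "", [])
        k = 0
        for radius, n in ((5.0, 200), (7.0, 320)):
            pts = rng.normal(size=(n, 3))
            pts = radius * pts / np.linalg.norm(pts, axis=1, keepdims=True)
            for p in pts:
                shell_res.atoms.append(sio.Atom("CB", "C", p))
                k += 1
        center.chains.append(sio.Chain("B", [shell_res]))
        rsa = sio.relative_solvent_accessibility(center, sio.ResidueRef("A", 1))
        assert rsa < 0.05

    def test_per_residue_sasa_sums_to_total(self, toy_complex):
        per_res = sio.residue_sasa(toy_complex)
        total = sio.atom_sasa(toy_complex).sum()
        assert abs(sum(per_res.values()) - total) / total < 0.01

    def test_against_biopython_shrake_rupley(self, toy_complex, tmp_path):
        """Independent SASA oracle: Bio.PDB's Shrake-Rupley on the same file."""
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        path = tmp_path / "sasa.pdb"
        sio.write_pdb(toy_complex, path)
        bp = PDBParser(QUIET=True).get_structure("t", str(path))
        ShrakeRupley(probe_radius=1.4, n_points=960).compute(bp, level="S")
        ours = sio.atom_sasa(toy_complex).sum()
        theirs = bp.sasa
        assert abs(ours - theirs) / theirs < 0.03

    def test_unknown_residue_type_raises(self):
        s = _single_residue("GLY", [("N", "N", (0, 0, 0)),
                                    ("CA", "C", (1.4, 0, 0))])
        s.chains[0].residues[0].name = "UNK"
        with pytest.raises(ValueError, match="UNK"):
            sio.relative_solvent_accessibility(s, sio.ResidueRef("A", 1))


class TestPhi:
    def test_chain_start_undefined(self, toy_complex):
        assert np.isnan(sio.phi_torsion(toy_complex, sio.ResidueRef("A", 1)))

    def test_planar_trans_geometry_is_180(self):
        # zigzag in the z=0 plane: dihedral of coplanar trans atoms
        res1 = sio.Residue("ALA", 1, "", [
            sio.Atom("N", "N", np.array([-2.4, 1.0, 0.0])),
            sio.Atom("CA", "C", np.array([-1.9, 0.0, 0.0])),
            sio.Atom("C", "C", np.array([0.0, 0.0, 0.0]))])
        res2 = sio.Residue("ALA", 2, "", [
            sio.Atom("N", "N", np.array([0.7, 1.1, 0.0])),
            sio.Atom("CA", "C", np.array([2.1, 1.1, 0.0])),
            sio.Atom("C", "C", np.array([2.8, 2.2, 0.0]))])
        s = sio.Structure("t", [sio.Chain("A", [res1, res2])])
        phi = sio.phi_torsion(s, sio.ResidueRef("A", 2))
        assert abs(abs(phi) - 180.0) < 1e-6

    def test_alpha_helix_phi(self):
        h = sio.make_helix(10)
        for i in (3, 4, 5):
            assert sio.phi_torsion(h, sio.ResidueRef("A", i)) == pytest.approx(
                -57.0, abs=3.0)

    def test_missing_backbone_warns_and_returns_nan(self, toy_complex):
        s = toy_complex.copy()
        res = s.get_residue(sio.ResidueRef("A", 3))
        res.atoms = [a for a in res.atoms if a.name != "N"]
        with pytest.warns(UserWarning):
            assert np.isnan(sio.phi_torsion(s, sio.ResidueRef("A", 3)))


class TestDepth:
    def test_surface_residue_is_shallow(self, toy_complex):
        assert sio.residue_depth(toy_complex, sio.ResidueRef("A", 3)) < 3.0

    def test_buried_center_of_solid_ball(self):
        # solid ball of atoms, radius 15 A, residue at the center
        grid = np.arange(-15.0, 15.1, 1.8)
        pts = np.array([[x, y, z] for x in grid for y in grid for z in grid
                        if x * x + y * y + z * z <= 15.0 ** 2
                        and x * x + y * y + z * z > 2.0 ** 2])
        ball = sio.Residue("ALA", 1, "", [sio.Atom("CB", "C", p) for p in pts])
        center = sio.Residue("GLY", 1, "", [
            sio.Atom("N", "N", np.array([0.0, 0.0, 0.0])),
            sio.Atom("CA", "C", np.array([1.0, 0.0, 0.0]))])
        s = sio.Structure("ball", [sio.Chain("A", [center]),
                                   sio.Chain("B", [ball])])
        depth = sio.residue_depth(s, sio.ResidueRef("A", 1))
        # brute-force oracle: nearest surface atom over the residue's atoms
        sasa = sio.atom_sasa(s)
        surface = np.array([a.coord for (_, _, a), v
                            in zip(s.heavy_atoms(), sasa) if v > 0])
        oracle = np.mean([np.linalg.norm(surface - c, axis=1).min()
                          for c in [np.zeros(3), np.array([1.0, 0, 0])]])
        assert depth == pytest.approx(oracle, abs=1e-9)
        assert depth >= 10.0

    def test_rigid_motion_invariance(self, toy_complex):
        rng = np.random.default_rng(5)
        moved = toy_complex.transformed(random_rotation(rng),
                                        rng.normal(size=3) * 20)
        ref = sio.ResidueRef("A", 4)
        d0 = sio.residue_depth(toy_complex, ref)
        d1 = sio.residue_depth(moved, ref)
        # surface-set membership is sampling-limited, hence the loose band
        assert d1 == pytest.approx(d0, abs=0.05)


class TestComposition:
    @pytest.mark.parametrize("seq,slot,expected", [
        ("AAAA", "A", 1.0),
        ("ACDEFGHIKLMNPQRSTVWY", "W", 0.05),
        ("AAX", "A", 1.0),
    ])
    def test_known_compositions(self, seq, slot, expected):
        from ppiddg.data import ALPHABET
        vec = sio.aa_composition(seq)
        assert vec[ALPHABET.index(slot)] == pytest.approx(expected)
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            sio.aa_composition("")
        with pytest.raises(ValueError):
            sio.aa_composition("AB1")


class TestToyComplex:
    def test_determinism(self):
        a = sio.make_toy_complex(5, 4.0, 42)
        b = sio.make_toy_complex(5, 4.0, 42)
        for (_, _, x), (_, _, y) in zip(a.heavy_atoms(), b.heavy_atoms()):
            assert np.array_equal(x.coord, y.coord)

    @pytest.mark.parametrize("gap", [3.0, 4.0, 5.0, 8.0])
    def test_gap_calibration(self, gap):
        s = sio.make_toy_complex(5, gap, 42)
        xa = np.array([a.coord for _, r, a in s.heavy_atoms()
                       if _.id == "A"])
        xb = np.array([a.coord for _, r, a in s.heavy_atoms()
                       if _.id == "B"])
        dmin = np.linalg.norm(xa[:, None] - xb[None, :], axis=-1).min()
        assert gap - 0.1 <= dmin <= gap + 0.1

    def test_minimal_complex(self):
        s = sio.make_toy_complex(1, 10.0, 1)
        assert len(s.chains) == 2
        assert all(len(c.residues) == 1 for c in s.chains)

    def test_substituted_sequences(self, toy_complex):
        assert toy_complex.chain("A").sequence() == "AFKDSA"
        assert toy_complex.chain("B").sequence() == "AWENTA"
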