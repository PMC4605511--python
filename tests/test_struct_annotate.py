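import numpy as np
import pytest

from palinscan.palindrome_scan import PalindromeHit
from palinscan.struct_annotate import (assign_secondary_structure,
                                       average_sasa, count_contacts,
                                       functional_interactions,
                                       shrake_rupley_sasa)
from palinscan.structure_io import Atom, Residue, StructureModel
from palinscan.synthetic_data import GeometrySpec, build_ideal_peptide

from .conftest import reference_dssp


def simple_residue(chain, num, name3, one, atom_specs):
    return Residue(chain, num, "", name3, one,
                   atoms=[Atom(n, el, np.asarray(c, float)) for n, el, c in atom_specs],
                   is_complete=True)


class TestSecondaryStructure:
    def test_ideal_helix_interior_H(self, helix16, tmp_path):
        ss = assign_secondary_structure(helix16, "A")
        interior = ss[2:-2]
        assert interior.count("H") / len(interior) >= 0.9
        # exact agreement with the reference DSSP implementation
        assert ss == reference_dssp(helix16, tmp_path)["A"]

    def test_hairpin_strand_cores(self, hairpin, tmp_path):
        ss = assign_secondary_structure(hairpin, "A")
        ref = reference_dssp(hairpin, tmp_path)["A"]
        assert ss == ref
        # strand cores are E on both strands
        assert ss[1:5] == "EEEE" and ss[7:11] == "EEEE"

    def test_two_residue_chain_no_regular_structure(self):
        model = build_ideal_peptide(GeometrySpec(sequence="AA",
                                                 conformer="helix"))
        ss = assign_secondary_structure(model, "A")
        assert set(ss) <= {"C", "S", "-"}

    def test_missing_backbone_gets_dash(self, helix16):
        import copy
        model = copy.deepcopy(helix16)
        res = model.chains["A"][8]
        res.atoms = [a for a in res.atoms if a.name not in ("O", "C")]
        ss = assign_secondary_structure(model, "A")
        assert ss[8] == "-"

    def test_dssp_map_takes_precedence(self, helix16):
        dssp_map = {("A", r.seq_number, r.insertion_code): "E"
                    for r in helix16.chains["A"][:8]}
        ss = assign_secondary_structure(helix16, "A", dssp_map=dssp_map)
        assert ss == "E" * 8 + "-" * 8


class TestSasa:
    def test_lone_carbon_analytic(self, lone_carbon):
        profile = shrake_rupley_sasa(lone_carbon, n_points=960)
        analytic = 4 * np.pi * (1.7 + 1.4) ** 2
        assert profile.values[("A", 1, "")] == pytest.approx(analytic,
                                                             rel=0.01)

    def test_buried_atom_zero(self):
        # carbon enclosed in a dense cage of carbons
        cage = []
        k = 2
        pts = []
        for theta in np.linspace(0, np.pi, 10):
            for phi in np.linspace(0, 2 * np.pi, 20, endpoint=False):
                pts.append([3.0 * np.sin(theta) * np.cos(phi),
                            3.0 * np.sin(theta) * np.sin(phi),
                            3.0 * np.cos(theta)])
        atoms = [("C", "C", [0, 0, 0])] + [(f"C", "C", p) for p in pts]
        res = Residue("A", 1, "", "UNK", "X",
                      atoms=[Atom("CA", "C", np.zeros(3))])
        cage_res = Residue("A", 2, "", "UNK", "X",
                           atoms=[Atom("C", "C", np.asarray(p)) for p in pts])
        model = StructureModel(pdb_id="CAGE",
                               chains={"A": [res, cage_res]})
        profile = shrake_rupley_sasa(model, n_points=960)
        assert profile.values[("A", 1, "")] == pytest.approx(0.0, abs=1e-9)

    def test_rotation_invariance(self, helix16):
        import copy
        total = sum(shrake_rupley_sasa(helix16, n_points=3840).values.values())
        rotated = copy.deepcopy(helix16)
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        for res in rotated.chains["A"]:
            for atom in res.atoms:
                atom.coords = rot.apply(atom.coords) + np.array([5.0, -3.0, 2.0])
        total_rot = sum(shrake_rupley_sasa(rotated,
                                           n_points=3840).values.values())
        assert total_rot == pytest.approx(total, rel=1e-3)

    def test_quadrature_convergence(self, helix16):
        t960 = sum(shrake_rupley_sasa(helix16, n_points=960).values.values())
        t3840 = sum(shrake_rupley_sasa(helix16, n_points=3840).values.values())
        assert abs(t3840 - t960) / t3840 < 0.01

    def test_against_biopython_oracle(self, helix16, tmp_path):
        """Independent cross-check: Bio.PDB's Shrake-Rupley on the same file."""
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        from palinscan.structure_io import write_pdb
        path = tmp_path / "helix.pdb"
        write_pdb(helix16, path)
        structure = PDBParser(QUIET=True).get_structure("x", str(path))
        ShrakeRupley(probe_radius=1.4, n_points=960).compute(
            structure, level="R")
        ref = {r.id[1]: r.sasa for r in structure.get_residues()}
        mine = shrake_rupley_sasa(helix16, n_points=960).values
        for (chain, num, icode), value in mine.items():
            assert value == pytest.approx(ref[num], rel=0.05, abs=1.0)

    def test_average_sasa_arithmetic(self, helix16):
        profile = shrake_rupley_sasa(helix16, n_points=240)
        keys = [r.key for r in helix16.chains["A"][:5]]
        profile.values.update(dict.fromkeys(profile.values, 0.0))
        profile.values[keys[0]] = 10.0
        hit = PalindromeHit("SYN2", "A", 0, "AAAAA")
        assert average_sasa(helix16, hit, profile) == pytest.approx(2.0)

    def test_missing_residue_in_profile(self, helix16):
        profile = shrake_rupley_sasa(helix16, n_points=240)
        del profile.values[("A", 3, "")]
        hit = PalindromeHit("SYN2", "A", 0, "AAAAA")
        with pytest.raises(ValueError, match="missing"):
            average_sasa(helix16, hit, profile)


def contact_fixture():
    """Hit residue at origin plus two source residues: one with atoms at 2.9
    and 3.1 Å (counts once), one at 3.5 Å (not counted)."""
    hit_res = simple_residue("A", 1, "GLY", "G",
                             [("CA", "C", [0, 0, 0]), ("C", "C", [1.5, 0, 0])])
    near = simple_residue("A", 5, "GLY", "G",
                          [("CA", "C", [0, 2.9, 0]), ("C", "C", [0, 3.1, 0])])
    far = simple_residue("A", 9, "GLY", "G", [("CA", "C", [0, 0, 3.5])])
    return StructureModel(pdb_id="CONT",
                          chains={"A": [hit_res, near, far]})


class TestContacts:
    def test_counted_once_and_cutoff(self):
        model = contact_fixture()
        # window length is irrelevant to the counting rule: 1-residue "hit"
        hit = PalindromeHit("CONT", "A", 0, "G")
        summary = count_contacts(model, hit, cutoff=3.2)
        assert summary.n_contact_residues == 1
        assert summary.contacts == [("A", 5, "")]

    def test_monotone_in_cutoff(self):
        model = contact_fixture()
        hit = PalindromeHit("CONT", "A", 0, "G")
        counts = [count_contacts(model, hit, cutoff=c).n_contact_residues
                  for c in (2.0, 3.2, 4.0)]
        assert counts == sorted(counts)

    def test_no_sources_zero(self):
        hit_res = simple_residue("A", 1, "GLY", "G", [("CA", "C", [0, 0, 0])])
        model = StructureModel(pdb_id="X", chains={"A": [hit_res]})
        hit = PalindromeHit("X", "A", 0, "G")
        assert count_contacts(model, hit).n_contact_residues == 0

    def test_cross_chain_sources_count(self):
        hit_res = simple_residue("A", 1, "GLY", "G", [("CA", "C", [0, 0, 0])])
        other = simple_residue("B", 1, "GLY", "G", [("CA", "C", [0, 0, 3.0])])
        model = StructureModel(pdb_id="X",
                               chains={"A": [hit_res], "B": [other]})
        hit = PalindromeHit("X", "A", 0, "G")
        assert count_contacts(model, hit).n_contact_residues == 1


class TestInteractions:
    def test_metal_flag(self):
        hit_res = simple_residue("A", 1, "HIS", "H",
                                 [("NE2", "N", [0, 0, 0])])
        zn = Residue("A", 90, "", "ZN", "X",
                     atoms=[Atom("ZN", "Zn", np.array([0, 0, 2.1]),
                                 is_hetero=True)])
        model = StructureModel(pdb_id="X", chains={"A": [hit_res]},
                               het_residues=[zn])
        hit = PalindromeHit("X", "A", 0, "H")
        flags = functional_interactions(model, hit)
        assert flags.metal and not flags.ligand

    def test_all_false_without_het_or_sites(self, helix16):
        hit = PalindromeHit("SYN2", "A", 0, "AAAAA")
        flags = functional_interactions(helix16, hit)
        assert not flags.any

    def test_disulphide(self):
        c1 = simple_residue("A", 1, "CYS", "C",
                            [("CA", "C", [0, 0, 0]), ("SG", "S", [1.8, 0, 0])])
        c2 = simple_residue("A", 30, "CYS", "C",
                            [("CA", "C", [4.8, 0, 0]),
                             ("SG", "S", [3.85, 0, 0])])
        model = StructureModel(pdb_id="X", chains={"A": [c1, c2]})
        hit = PalindromeHit("X", "A", 0, "C")
        flags = functional_interactions(model, hit)
        assert flags.disulphide

    def test_site_record_direct_membership(self):
        hit_res = simple_residue("A", 10, "GLY", "G",
                                 [("CA", "C", [0, 0, 0])])
        model = StructureModel(pdb_id="X", chains={"A": [hit_res]},
                               site_records={"AC1": [("A", 10, "")]})
        hit = PalindromeHit("X", "A", 0, "G")
        assert functional_interactions(model, hit).site_or_catalytic

    def test_catalytic_list_contact_and_warning(self):
        hit_res = simple_residue("A", 1, "GLY", "G", [("CA", "C", [0, 0, 0])])
        cat = simple_residue("A", 50, "SER", "S", [("CA", "C", [0, 3.0, 0])])
        model = StructureModel(pdb_id="X", chains={"A": [hit_res, cat]})
        hit = PalindromeHit("X", "A", 0, "G")
        flags = functional_interactions(model, hit,
                                        catalytic_list=[("A", 50, "")])
        assert flags.site_or_catalytic
        with pytest.warns(UserWarning, match="not found"):
            functional_interactions(model, hit,
                                    catalytic_list=[("Z", 999, "")])

    def test_ligand_flag_and_water_ignored(self):
        hit_res = simple_residue("A", 1, "GLY", "G", [("CA", "C", [0, 0, 0])])
        lig = Residue("A", 91, "", "NAG", "X",
                      atoms=[Atom("C1", "C", np.array([0, 3.0, 0]),
                                  is_hetero=True)])
        wat = Residue("A", 99, "", "HOH", "X", is_water=True,
                      atoms=[Atom("O", "O", np.array([0, 0, 2.5]),
                                  is_hetero=True)])
        model = StructureModel(pdb_id="X", chains={"A": [hit_res]},
                               het_residues=[lig, wat])
        hit = PalindromeHit("X", "A", 0, "G")
        flags = functional_interactions(model, hit)
        assert flags.ligand and not flags.metal
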