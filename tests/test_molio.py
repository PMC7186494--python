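"""Structure and pose I/O: PDB round trips, element inference, formal
charges, water/ion retention."""

import numpy as np
import pytest

from qmrescore import (
    DockedPose,
    LibraryManifest,
    MolecularSystem,
    assign_formal_charges,
    make_toy_pocket,
    read_manifest,
    read_pdb,
    read_poses,
    select_environment,
    write_manifest,
    write_pdb,
    write_sdf,
)
from qmrescore.core import Atom
from qmrescore.molio import ParseError, infer_element

PEPTIDE_PDB = """\
ATOM      1  N   ASP A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ASP A   1       1.470   0.000   0.000  1.00  0.00           C
ATOM      3  C   ASP A   1       2.000   1.430   0.000  1.00  0.00           C
ATOM      4  O   ASP A   1       1.400   2.300   0.700  1.00  0.00           O
ATOM      5  CB  ASP A   1       2.000  -0.800  -1.200  1.00  0.00           C
ATOM      6  N   ALA A   2       3.300   1.600   0.100  1.00  0.00           N
ATOM      7  CA  ALA A   2       3.900   2.900   0.200  1.00  0.00           C
ATOM      8  C   ALA A   2       5.400   2.800   0.100  1.00  0.00           C
ATOM      9  O   ALA A   2       6.000   1.800  -0.400  1.00  0.00           O
ATOM     10  CB  ALA A   2       3.400   3.800   1.400  1.00  0.00           C
ATOM     11  N   LYS A   3       6.100   3.800   0.600  1.00  0.00           N
ATOM     12  CA  LYS A   3       7.500   3.900   0.600  1.00  0.00           C
ATOM     13  C   LYS A   3       8.100   5.300   0.700  1.00  0.00           C
ATOM     14  O   LYS A   3       7.400   6.300   0.900  1.00  0.00           O
ATOM     15  CB  LYS A   3       8.200   3.100  -0.600  1.00  0.00           C
HETATM   16  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
END
"""

CA_AMBIGUITY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00
ATOM      2  CA  GLY A   1       1.470   0.000   0.000  1.00  0.00
ATOM      3  C   GLY A   1       2.000   1.430   0.000  1.00  0.00
ATOM      4  O   GLY A   1       1.400   2.300   0.700  1.00  0.00
HETATM    5 CA    CA A 201       8.000   8.000   8.000  1.00  0.00
HETATM    6  O   HOH A 301       3.000   3.000   3.000  1.00  0.00
"""


@pytest.fixture
def peptide(tmp_path):
    p = tmp_path / "peptide.pdb"
    p.write_text(PEPTIDE_PDB)
    return read_pdb(p)


class TestReadPdb:
    def test_water_classified_by_residue_name(self, peptide):
        classes = {a.record_class for a in peptide.atoms}
        assert "water" in classes
        waters = [a for a in peptide.atoms if a.record_class == "water"]
        assert len(waters) == 1 and waters[0].res_name == "HOH"

    def test_peptide_bonds_inferred_between_consecutive_residues(self, peptide):
        names = [(peptide.atoms[i].name, peptide.atoms[j].name) for i, j, _ in peptide.bonds]
        assert ("C", "N") in names or ("N", "C") in names

    def test_element_inferred_when_column_missing(self, tmp_path):
        p = tmp_path / "noelem.pdb"
        p.write_text(CA_AMBIGUITY_PDB)
        system = read_pdb(p)
        by_name = {(a.res_name, a.name): a for a in system.atoms}
        assert by_name[("GLY", "CA")].element == "C"  # alpha carbon
        assert by_name[("CA", "CA")].element == "Ca"  # calcium in its own residue
        assert by_name[("CA", "CA")].record_class == "ion"

    def test_malformed_record_error_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  N   ASP A   1       xxx     0.000   0.000\n")
        with pytest.raises(ParseError, match="line 1"):
            read_pdb(p)

    def test_unknown_element_rejected(self, tmp_path):
        p = tmp_path / "weird.pdb"
        line = PEPTIDE_PDB.splitlines()[0][:76] + "Xx"
        p.write_text(line + "\n")
        with pytest.raises(ParseError, match="element"):
            read_pdb(p)

    @pytest.mark.parametrize(
        "name,res,het,expected",
        [
            ("1HB", "ASP", False, "H"),
            ("HG11", "VAL", False, "H"),
            ("CL", "CL", True, "Cl"),
            ("ZN", "ZN", True, "Zn"),
            ("CD", "ILE", False, "C"),
        ],
    )
    def test_element_rule_table(self, name, res, het, expected):
        assert infer_element(name, res, het) == expected


class TestRoundTrip:
    def test_pdb_round_trip_preserves_structure(self, tmp_path, charged_pocket):
        p1 = tmp_path / "a.pdb"
        p2 = tmp_path / "b.pdb"
        write_pdb(charged_pocket, p1)
        again = read_pdb(p1)
        write_pdb(again, p2)
        third = read_pdb(p2)
        assert len(again.atoms) == len(charged_pocket.atoms)
        assert [a.element for a in again.atoms] == [a.element for a in charged_pocket.atoms]
        assert again.total_charge == charged_pocket.total_charge
        np.testing.assert_allclose(again.coords, charged_pocket.coords, atol=1e-3)
        np.testing.assert_allclose(third.coords, again.coords, atol=1e-3)

    def test_cap_class_survives_round_trip(self, tmp_path):
        atom = Atom("H", "HCP", [0.0, 0.0, 0.0], record_class="cap")
        system = MolecularSystem(atoms=[atom])
        path = tmp_path / "cap.pdb"
        write_pdb(system, path)
        assert read_pdb(path).atoms[0].record_class == "cap"


class TestPoses:
    def _manifest(self, n=3, label="ligand"):
        return LibraryManifest.from_records(
            [(f"m{i}_s1", f"m{i}", label) for i in range(n)]
        )

    def _poses(self, small_library):
        poses, _ = small_library
        return poses

    def test_sdf_round_trip_with_labels(self, tmp_path, small_library):
        poses, manifest = small_library
        path = tmp_path / "lib.sdf"
        write_sdf(poses, path)
        again = read_poses(path, manifest)
        assert len(again) == len(poses)
        assert [p.state_id for p in again] == [p.state_id for p in poses]
        assert [p.is_ligand for p in again] == [p.is_ligand for p in poses]
        for a, b in zip(again, poses):
            assert len(a.ligand.atoms) == len(b.ligand.atoms)
            assert a.ligand.total_charge == b.ligand.total_charge
            np.testing.assert_allclose(a.ligand.coords, b.ligand.coords, atol=1e-3)

    def test_charge_block_propagated(self, tmp_path):
        sdf = (
            "chg_s1\n     RDKit          3D\n\n"
            "  2  1  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0\n"
            "    1.4000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
            "  1  2  1  0\nM  CHG  1   1   1\nM  END\n$$$$\n"
        )
        path = tmp_path / "chg.sdf"
        path.write_text(sdf)
        manifest = LibraryManifest.from_records([("chg_s1", "chg", "ligand")])
        (pose,) = read_poses(path, manifest)
        assert pose.ligand.total_charge == 1

    def test_mol2_matches_sdf_record(self, tmp_path):
        mol2 = (
            "@<TRIPOS>MOLECULE\nchg_s1\n 2 1 0 0 0\nSMALL\nNO_CHARGES\n"
            "@<TRIPOS>ATOM\n"
            "  1 N1  0.0000 0.0000 0.0000 N.3\n"
            "  2 C1  1.4000 0.0000 0.0000 C.3\n"
            "@<TRIPOS>BOND\n  1 1 2 1\n"
        )
        path = tmp_path / "m.mol2"
        path.write_text(mol2)
        manifest = LibraryManifest.from_records([("chg_s1", "chg", "ligand")])
        (pose,) = read_poses(path, manifest)
        heavy = [a for a in pose.ligand.atoms if a.is_heavy]
        assert len(heavy) == 2
        assert pose.ligand.total_charge == 0

    def test_missing_manifest_row_raises(self, tmp_path, small_library):
        poses, _ = small_library
        path = tmp_path / "lib.sdf"
        write_sdf(poses[:1], path)
        empty = LibraryManifest.from_records([])
        with pytest.raises(ParseError, match=poses[0].state_id):
            read_poses(path, empty)

    def test_manifest_round_trip(self, tmp_path, small_library):
        _, manifest = small_library
        path = tmp_path / "manifest.tsv"
        write_manifest(manifest, path)
        again = read_manifest(path)
        assert again.rows == manifest.rows

    def test_duplicate_state_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            LibraryManifest.from_records(
                [("s1", "m1", "ligand"), ("s1", "m2", "decoy")]
            )


class TestFormalCharges:
    def test_asp_lys_cancel(self, tmp_path):
        p = tmp_path / "pep.pdb"
        p.write_text(PEPTIDE_PDB)
        charged = assign_formal_charges(read_pdb(p))
        assert charged.total_charge == 0  # one Asp (-1) + one Lys (+1)

    def test_two_glu_one_arg(self):
        pocket = make_toy_pocket(seed=3, n_residues=8)
        # cycle ASP ALA LYS SER GLU ALA ARG SER -> net 0
        assert assign_formal_charges(pocket).total_charge == 0

    def test_calcium_contributes_plus_two(self, tmp_path):
        p = tmp_path / "ca.pdb"
        p.write_text(CA_AMBIGUITY_PDB)
        charged = assign_formal_charges(read_pdb(p))
        ion = [a for a in charged.atoms if a.record_class == "ion"]
        assert len(ion) == 1 and ion[0].formal_charge == 2
        assert charged.total_charge == 2

    def test_idempotent(self, pocket):
        once = assign_formal_charges(pocket)
        twice = assign_formal_charges(once)
        assert [a.formal_charge for a in once.atoms] == [
            a.formal_charge for a in twice.atoms
        ]

    def test_nonstandard_residue_warns_and_zeroes(self, caplog):
        atom = Atom("C", "CA", [0.0, 0.0, 0.0], res_name="XYZ", record_class="protein")
        system = MolecularSystem(atoms=[atom])
        with caplog.at_level("WARNING"):
            charged = assign_formal_charges(system)
        assert charged.total_charge == 0
        assert "XYZ" in caplog.text


class TestSelectEnvironment:
    def _receptor_with_waters(self, distances, cls="water"):
        atoms = [Atom("C", "CA", [0.0, 0.0, 0.0], res_name="ALA", res_seq=1,
                      record_class="protein")]
        for k, d in enumerate(distances):
            res = "HOH" if cls == "water" else "CA"
            el = "O" if cls == "water" else "Ca"
            atoms.append(
                Atom(el, el.upper(), [d, 0.0, 0.0], res_name=res, res_seq=100 + k,
                     record_class=cls)
            )
        return MolecularSystem(atoms=atoms)

    def _ligand(self):
        return MolecularSystem(
            atoms=[Atom("C", "C1", [0.0, 0.0, 0.0], record_class="ligand")]
        )

    def test_water_boundary_at_4A(self):
        rec = self._receptor_with_waters([3.9, 4.1])
        out = select_environment(rec, self._ligand())
        kept = [a for a in out.atoms if a.record_class == "water"]
        assert len(kept) == 1 and kept[0].coords[0] == pytest.approx(3.9)

    def test_ion_kept_within_8A(self):
        rec = self._receptor_with_waters([7.9, 8.4], cls="ion")
        out = select_environment(rec, self._ligand())
        kept = [a for a in out.atoms if a.record_class == "ion"]
        assert len(kept) == 1 and kept[0].coords[0] == pytest.approx(7.9)

    def test_no_waters_identity(self, charged_pocket):
        out = select_environment(charged_pocket, self._ligand())
        assert len(out.atoms) == len(charged_pocket.atoms)

    def test_no_reference_drops_all(self):
        rec = self._receptor_with_waters([1.0, 2.0])
        out = select_environment(rec, None)
        assert all(a.record_class != "water" for a in out.atoms)

    def test_monotone_in_cutoff(self):
        rec = self._receptor_with_waters([1.0, 3.0, 5.0, 7.0])
        small = select_environment(rec, self._ligand(), water_cutoff=2.0)
        large = select_environment(rec, self._ligand(), water_cutoff=6.0)
        assert len(large.atoms) >= len(small.atoms)
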