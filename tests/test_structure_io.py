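"""PDB / STRIDE parsing, alt-loc and model handling, joins, round trips."""

import numpy as np
import pytest

import pslflex as pf
from pslflex.errors import FormatError, JoinError, StructureError

from conftest import THREE_RESIDUE_PDB, atom_line


class TestParsePdb:
    def test_calpha_skeleton_and_bfactors(self, three_residue_pdb):
        st = pf.parse_pdb(three_residue_pdb)
        assert len(st.calpha) == 3
        assert np.allclose(st.b_factors, [10.0, 20.0, 30.0])
        assert all(a.name == "CA" for a in st.calpha)

    def test_heavy_atom_count(self, three_residue_pdb):
        st = pf.parse_pdb(three_residue_pdb)
        assert st.global_features.n_heavy_atoms == 5
        # independent line-level scan of the fixture text
        n_lines = sum(
            1 for line in THREE_RESIDUE_PDB.splitlines() if line.startswith("ATOM")
        )
        assert st.global_features.n_heavy_atoms == n_lines

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        text = "\n".join(
            [
                atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.4, b=5.0, altloc="A"),
                atom_line(2, "CA", "ALA", "A", 1, 0.1, 0.0, 0.0, occ=0.6, b=6.0, altloc="B"),
                "END",
            ]
        )
        path = tmp_path / "alt.pdb"
        path.write_text(text + "\n")
        st = pf.parse_pdb(path)
        assert len(st.calpha) == 1
        assert st.calpha[0].occupancy == pytest.approx(0.6)
        assert st.calpha[0].b_factor == pytest.approx(6.0)

    def test_altloc_tie_breaks_lexicographically(self, tmp_path):
        text = "\n".join(
            [
                atom_line(1, "CA", "ALA", "A", 1, 0.2, 0.0, 0.0, occ=0.5, b=7.0, altloc="B"),
                atom_line(2, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.5, b=5.0, altloc="A"),
                "END",
            ]
        )
        path = tmp_path / "tie.pdb"
        path.write_text(text + "\n")
        st = pf.parse_pdb(path)
        assert st.calpha[0].b_factor == pytest.approx(5.0)

    def test_hetatm_and_hydrogens_excluded(self, tmp_path):
        text = "\n".join(
            [
                atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, b=10.0),
                atom_line(2, "H", "ALA", "A", 1, 0.5, 0.5, 0.0, element="H"),
                atom_line(3, "O", "HOH", "A", 2, 5.0, 5.0, 5.0, element="O", record="HETATM"),
                "END",
            ]
        )
        path = tmp_path / "het.pdb"
        path.write_text(text + "\n")
        st = pf.parse_pdb(path)
        assert st.global_features.n_heavy_atoms == 1

    def test_first_model_only(self, tmp_path):
        text = "\n".join(
            [
                "MODEL        1",
                atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, b=10.0),
                "ENDMDL",
                "MODEL        2",
                atom_line(1, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, b=99.0),
                "ENDMDL",
                "END",
            ]
        )
        path = tmp_path / "models.pdb"
        path.write_text(text + "\n")
        st = pf.parse_pdb(path)
        assert len(st.calpha) == 1
        assert st.calpha[0].b_factor == pytest.approx(10.0)

    def test_no_calpha_raises(self, tmp_path):
        path = tmp_path / "noca.pdb"
        path.write_text(atom_line(1, "N", "ALA", "A", 1, 0, 0, 0, element="N") + "\nEND\n")
        with pytest.raises(StructureError):
            pf.parse_pdb(path)

    def test_order_invariant_to_line_permutation(self, tmp_path):
        lines = [
            atom_line(1, "N", "ALA", "A", 1, 0.0, 1.0, 0.0, element="N"),
            atom_line(2, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, b=10.0),
            atom_line(3, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0, b=20.0),
        ]
        a, b = tmp_path / "a.pdb", tmp_path / "b.pdb"
        a.write_text("\n".join(lines) + "\nEND\n")
        b.write_text("\n".join([lines[1], lines[0], lines[2]]) + "\nEND\n")
        sa, sb = pf.parse_pdb(a), pf.parse_pdb(b)
        assert [x.residue_seq for x in sa.calpha] == [x.residue_seq for x in sb.calpha]
        assert np.allclose(sa.ca_coordinates, sb.ca_coordinates)

    def test_roundtrip_through_written_pdb(self, tmp_path):
        protein = pf.synth_structure(
            pf.SyntheticSpec(n_residues=12, geometry="coil", seed=5)
        )
        path = tmp_path / "rt.pdb"
        pf.write_pdb(protein.structure, path)
        st = pf.parse_pdb(path)
        assert np.allclose(st.ca_coordinates, protein.structure.ca_coordinates, atol=1e-3)
        assert np.allclose(
            st.b_factors, np.round(protein.structure.b_factors, 2), atol=1e-9
        )
        assert np.allclose([a.occupancy for a in st.heavy_atoms], 1.0)


class TestGlobalHeader:
    def test_resolution_and_rvalue(self, three_residue_pdb):
        g = pf.parse_global_header(three_residue_pdb)
        assert g.resolution == pytest.approx(1.70)
        assert g.r_value == pytest.approx(0.190)

    def test_missing_records_stay_missing(self, tmp_path):
        path = tmp_path / "bare.pdb"
        path.write_text(atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0) + "\nEND\n")
        g = pf.parse_global_header(path)
        assert g.resolution is None
        assert g.r_value is None

    def test_malformed_value_treated_as_missing(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "REMARK   2 RESOLUTION.    NOT ANGSTROMS.\n"
            "REMARK   3   R VALUE            (WORKING SET) : NULL\n"
        )
        g = pf.parse_global_header(path)
        assert g.resolution is None
        assert g.r_value is None


STRIDE_TEXT = """REM  --------------
ASG  ALA A    1    1    H    AlphaHelix   -57.80  -47.00    12.3
ASG  GLY A    2    2    b    Bridge       -80.00  120.00    40.0
ASG  SER A    3    3    Q    Unknown      -70.00  140.00    55.0
"""


class TestParseStride:
    def test_asg_echo_and_normalization(self, tmp_path):
        path = tmp_path / "s.stride"
        path.write_text(STRIDE_TEXT)
        with pytest.warns(UserWarning, match="unknown secondary-structure"):
            records = pf.parse_stride(path)
        assert len(records) == 3
        assert records[0].ss_code == "H"
        assert records[0].phi == pytest.approx(-57.80)
        assert records[0].psi == pytest.approx(-47.00)
        assert records[0].solvent_area == pytest.approx(12.3)
        assert records[1].ss_code == "B"  # lowercase b normalized
        assert records[2].ss_code == "C"  # unknown mapped to coil

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.stride"
        path.write_text("REM nothing here\n")
        with pytest.raises(FormatError):
            pf.parse_stride(path)


class TestJoinStride:
    def make_records(self, seqs):
        return [
            pf.StrideRecord("A", s, "ALA", "H", -60.0, -45.0, 10.0) for s in seqs
        ]

    def test_full_match(self, three_residue_pdb):
        st = pf.parse_pdb(three_residue_pdb)
        result = pf.join_stride(st, self.make_records([1, 2, 3]))
        assert len(result.unmatched) == 0
        assert not result.flagged
        assert all(r is not None for r in result.aligned)

    def test_partial_match_flagged(self, three_residue_pdb):
        st = pf.parse_pdb(three_residue_pdb)
        result = pf.join_stride(st, self.make_records([1, 2]))
        assert result.flagged
        assert len(result.unmatched) == 1

    def test_chain_mismatch_is_join_error(self, three_residue_pdb):
        st = pf.parse_pdb(three_residue_pdb)
        records = [pf.StrideRecord("B", s, "ALA", "H", -60.0, -45.0, 10.0) for s in (1, 2, 3)]
        with pytest.raises(JoinError):
            pf.join_stride(st, records)
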