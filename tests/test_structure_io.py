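"""Structure reading, header filters and fixture round trips."""

import numpy as np
import pytest

from catrace.structure_io import (CAlphaChain, EmptyRecordError,
                                  StructureParseError, StructureRecord,
                                  annotate_bonds, filter_keyword,
                                  read_structure, sample_random_subset,
                                  select_structures, write_entry_list,
                                  write_fixture)
from catrace.synthetic_data import make_coil, make_helix
from catrace.virtual_geometry import rebuild_chain


def rec(entry_id="AAAA", resolution=1.5, method="xray", keywords=""):
    return StructureRecord(entry_id=entry_id, resolution=resolution,
                           method=method, keywords=keywords)


class TestRoundTrip:
    def test_coordinates_flags_header(self, tmp_path, rng):
        ch = make_helix(15, flag_records=False)
        ch.helix_flag[3:9] = True
        ch.sheet_flag[11:14] = True
        path = write_fixture(ch, dict(entry_id="1FIX", resolution=1.5,
                                      method="xray",
                                      keywords="ALPHA HELIX, TEST"),
                             tmp_path / "f.pdb")
        out = read_structure(path)
        assert out.resolution == pytest.approx(1.50, abs=1e-9)
        assert out.method == "xray"
        assert out.keywords == "ALPHA HELIX, TEST"
        c2 = out.chains[0]
        assert np.allclose(c2.coords, ch.coords, atol=1e-3)
        assert np.array_equal(c2.helix_flag, ch.helix_flag)
        assert np.array_equal(c2.sheet_flag, ch.sheet_flag)

    def test_helix_range_flags_inclusive(self, tmp_path):
        ch = make_helix(20)
        ch.helix_flag[4:15] = True          # residues 5..15 -> 11 residues
        path = write_fixture(ch, dict(entry_id="1HEL", resolution=2.0),
                             tmp_path / "h.pdb")
        out = read_structure(path)
        assert out.helix_ranges == [("A", 5, 15)]
        assert int(out.chains[0].helix_flag.sum()) == 11

    def test_missing_resolution_is_absent(self, tmp_path):
        ch = make_helix(8)
        path = write_fixture(ch, dict(entry_id="1NOR", resolution=None,
                                      method="nmr"), tmp_path / "n.pdb")
        out = read_structure(path)
        assert out.resolution is None
        assert out.method == "nmr"

    def test_mmcif_read(self, tmp_path):
        cif = tmp_path / "m.cif"
        cif.write_text("""\
data_1CIF
_entry.id 1CIF
_exptl.method 'X-RAY DIFFRACTION'
_refine.pdbx_refine_id 'X-RAY DIFFRACTION'
_refine.ls_d_res_high 1.80
_struct_keywords.text 'ALLOSTERIC PROTEIN'
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . ALA A 1 1 ? 0.000 0.000 0.000 1.00 10.0 1 A 1
ATOM 2 C CA . ALA A 1 2 ? 3.800 0.000 0.000 1.00 10.0 2 A 1
ATOM 3 C CA . ALA A 1 3 ? 3.800 3.800 0.000 1.00 10.0 3 A 1
ATOM 4 C CA . ALA A 1 4 ? 0.000 3.800 0.000 1.00 10.0 4 A 1
""")
        out = read_structure(cif, fmt="mmcif")
        assert out.resolution == pytest.approx(1.80)
        assert out.method == "xray"
        assert "ALLO" in out.keywords
        assert out.chains[0].nres == 4

    def test_altloc_highest_occupancy(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00 10.00           C\n"
            "ATOM      2  CA AALA A   2       3.800   0.000   0.000"
            "  0.40 10.00           C\n"
            "ATOM      3  CA BALA A   2       3.900   0.100   0.000"
            "  0.60 10.00           C\n"
            "ATOM      4  CA  ALA A   3       5.000   3.500   0.000"
            "  1.00 10.00           C\n"
            "END\n")
        out = read_structure(pdb)
        # occupancy 0.60 copy wins
        assert out.chains[0].coords[1, 0] == pytest.approx(3.900, abs=1e-3)

    def test_residue_without_ca_dropped_and_empty_errors(self, tmp_path):
        pdb = tmp_path / "noca.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00 10.00           N\nEND\n")
        with pytest.raises(EmptyRecordError):
            read_structure(pdb)

    def test_unparseable_raises(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("loop_ this is not a structure\n")
        with pytest.raises((StructureParseError, EmptyRecordError)):
            read_structure(bad, fmt="mmcif")


class TestSelect:
    def test_resolution_boundary_inclusive(self):
        records = [rec(resolution=1.8), rec(resolution=2.0),
                   rec(resolution=2.4), rec(resolution=None)]
        kept = select_structures(records, max_resolution=2.0)
        assert kept == records[:2]

    def test_nmr_excluded(self):
        records = [rec(method="nmr", resolution=1.5), rec(resolution=1.5)]
        assert select_structures(records, exclude_nmr=True) == [records[1]]
        assert select_structures(records, exclude_nmr=False) == records

    def test_empty_and_monotone(self):
        assert select_structures([]) == []
        records = [rec(resolution=r) for r in (1.2, 1.7, 1.9, 2.3)]
        loose = select_structures(records, max_resolution=2.0)
        tight = select_structures(records, max_resolution=1.8)
        assert set(r.resolution for r in tight) <= set(
            r.resolution for r in loose)
        # idempotent
        assert select_structures(loose, max_resolution=2.0) == loose


class TestKeywordAndSubset:
    @pytest.mark.parametrize("keywords,token,kept", [
        ("ALLOSTERIC ENZYME", "ALLO", True),
        ("HYDROLASE", "ALLO", False),
        ("ALLOSTERY", "allo", True),       # case-insensitive
    ])
    def test_filter_keyword(self, keywords, token, kept):
        records = [rec(keywords=keywords)]
        assert (filter_keyword(records, token) == records) is kept

    def test_subset_reproducible_and_distinct(self):
        records = [rec(entry_id=f"{i:04d}") for i in range(1000)]
        a = sample_random_subset(records, 100, seed=1)
        b = sample_random_subset(records, 100, seed=1)
        c = sample_random_subset(records, 100, seed=2)
        assert a == b
        assert a != c
        assert len(set(r.entry_id for r in a)) == 100

    def test_subset_full_size_is_identity(self):
        records = [rec(entry_id=f"{i:04d}") for i in range(10)]
        assert set(r.entry_id for r in
                   sample_random_subset(records, 10, seed=0)) == set(
                       r.entry_id for r in records)
        with pytest.raises(ValueError):
            sample_random_subset(records, 11, seed=0)


class TestAnnotateBonds:
    def make_chain(self, distances):
        coords = np.zeros((len(distances) + 1, 3))
        coords[1:, 0] = np.cumsum(distances)
        return CAlphaChain("A", np.arange(1, len(coords) + 1),
                           ["ALA"] * len(coords), coords)

    def test_cis_break_and_trans(self):
        ch = annotate_bonds(self.make_chain([2.9, 3.80, 9.0]))
        assert ch.cis_flag.tolist() == [True, False, False]
        assert ch.break_flag.tolist() == [False, False, True]

    def test_pure_function_of_coords(self):
        ch1 = annotate_bonds(self.make_chain([3.8, 3.0]))
        ch2 = annotate_bonds(self.make_chain([3.8, 3.0]))
        assert np.array_equal(ch1.cis_flag, ch2.cis_flag)
        assert np.array_equal(ch1.break_flag, ch2.break_flag)


def test_entry_list_format(tmp_path):
    r = rec(entry_id="1ABC")
    r.chains = [make_helix(6, chain_id="A"), make_helix(6, chain_id="B")]
    path = write_entry_list([r], tmp_path / "list.txt")
    assert path.read_text().splitlines() == ["1ABC_A", "1ABC_B"]
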