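"""Structure domain types, PDB round trips, mutation codes, virtual Cβ."""

import numpy as np
import pytest

from igmi import (MutationSpec, ToySpec, get_cbeta, make_toy_complex,
                  parse_mutation_code, parse_pdb, write_pdb)
from igmi.structure import (AtomRecord, ComplexStructure, PdbParseError,
                            ResidueRecord, SampleRecord)

from conftest import rigid_motion

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   2.420   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.300   1.500   0.100  1.00  0.00           N
ATOM      6  CA  GLY A   2       4.000   2.700   0.400  1.00  0.00           C
ATOM      7  C   GLY A   2       5.400   2.300   0.900  1.00  0.00           C
ATOM      8  O   GLY A   2       5.700   1.100   1.000  1.00  0.00           O
END
"""


class TestParsePdb:
    def test_minimal_two_residue_file(self):
        st = parse_pdb(MINIMAL_PDB)
        assert st.n_residues == 2
        assert st.chain_ids == ["A"]
        assert all(r.complete for r in st.residues)
        assert [r.aa for r in st.residues] == ["A", "G"]

    def test_hetatm_only_is_an_error(self):
        text = ("HETATM    1  O   HOH A   1       0.000   0.000   0.000"
                "  1.00  0.00           O\nEND\n")
        with pytest.raises(PdbParseError, match="no standard residues"):
            parse_pdb(text)

    def test_malformed_coordinates_name_the_line(self):
        bad = MINIMAL_PDB.replace("1.458", "xx.xx")
        with pytest.raises(PdbParseError, match="line 2"):
            parse_pdb(bad)

    def test_shuffled_atom_lines_parse_identically(self):
        lines = MINIMAL_PDB.strip().splitlines()[:-1]
        shuffled = "\n".join([lines[2], lines[0], lines[3], lines[1]]
                             + lines[4:]) + "\nEND\n"
        a, b = parse_pdb(MINIMAL_PDB), parse_pdb(shuffled)
        for ra, rb in zip(a.residues, b.residues):
            assert [x.name for x in ra.atoms] == [x.name for x in rb.atoms]
            for xa, xb in zip(ra.atoms, rb.atoms):
                np.testing.assert_allclose(xa.coords, xb.coords)

    def test_altloc_keeps_highest_occupancy(self):
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.70  0.00           C\n"
            "ATOM      4  C   ALA A   1       2.500   1.400   0.000  1.00  0.00           C\n"
            "END\n")
        st = parse_pdb(text)
        ca = st.residues[0].atom("CA")
        assert ca.coords[0] == pytest.approx(2.000, abs=1e-6)


class TestWritePdb:
    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_identity(self, seed):
        """write→parse preserves coordinates to PDB field precision."""
        st = make_toy_complex(ToySpec(n_per_chain=8, seed=seed))
        st2 = parse_pdb(write_pdb(st))
        assert st2.n_residues == st.n_residues
        for ra, rb in zip(st.residues, st2.residues):
            assert ra.key == rb.key and ra.aa == rb.aa
            for xa, xb in zip(ra.atoms, rb.atoms):
                assert xa.name == xb.name
                np.testing.assert_allclose(xa.coords, xb.coords, atol=1.0e-3)

    def test_chain_order_follows_residue_order(self, toy_complex):
        text = write_pdb(toy_complex)
        chains = [ln[21] for ln in text.splitlines() if ln.startswith("ATOM")]
        assert chains == sorted(chains)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            ComplexStructure([])


class TestMutationCodes:
    @pytest.mark.parametrize("code,wt,chain,pos,mut", [
        ("AE315C", "A", "E", 315, "C"),
        ("GI234K", "G", "I", 234, "K"),
        ("YA1W", "Y", "A", 1, "W"),
    ])
    def test_parse(self, code, wt, chain, pos, mut):
        spec = parse_mutation_code(code)
        assert (spec.wt_aa, spec.chain_id, spec.resseq, spec.mut_aa) == \
            (wt, chain, pos, mut)
        assert spec.code == code

    @pytest.mark.parametrize("bad", ["AE315A", "XE315C", "AE31xC", "AC"])
    def test_malformed_or_identity_codes_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_mutation_code(bad)

    def test_reversed_swaps_types(self):
        assert parse_mutation_code("AE315C").reversed().code == "CE315A"


class TestCbeta:
    def test_explicit_cb_returned_unchanged(self, toy_complex):
        res = next(r for r in toy_complex.residues if r.aa != "G")
        np.testing.assert_array_equal(get_cbeta(res), res.coords("CB"))

    def test_virtual_cb_bond_length(self):
        """Ideal backbone → ‖Cβ - Cα‖ = 1.522 Å by construction."""
        res = parse_pdb(MINIMAL_PDB).residues[1]  # glycine
        cb = get_cbeta(res)
        assert np.linalg.norm(cb - res.coords("CA")) == \
            pytest.approx(1.522, abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_virtual_cb_rigid_equivariance(self, seed):
        st = make_toy_complex(ToySpec(n_per_chain=6, seed=3))
        gly = ResidueRecord("A", 99, "", "G",
                            [AtomRecord(a.name, a.element, a.coords.copy())
                             for a in st.residues[2].atoms
                             if a.name in ("N", "CA", "C")])
        moved = rigid_motion(
            ComplexStructure([gly], ({"A"}, set()) if False else None), seed)
        # rebuild the expected transform from CA atoms
        cb0 = get_cbeta(gly)
        cb1 = get_cbeta(moved.residues[0])
        # distances to backbone atoms are preserved under rigid motion
        for name in ("N", "CA", "C"):
            d0 = np.linalg.norm(cb0 - gly.coords(name))
            d1 = np.linalg.norm(cb1 - moved.residues[0].coords(name))
            assert d0 == pytest.approx(d1, abs=1e-6)

    def test_collinear_backbone_rejected(self):
        res = ResidueRecord("A", 1, "", "G", [
            AtomRecord("N", "N", np.array([0.0, 0, 0])),
            AtomRecord("CA", "C", np.array([1.0, 0, 0])),
            AtomRecord("C", "C", np.array([2.0, 0, 0]))])
        with pytest.raises(ValueError, match="collinear"):
            get_cbeta(res)


class TestSampleRecord:
    def test_valid_sample_and_reverse(self, toy_sample):
        rev = toy_sample.reversed()
        assert rev.ddg == -toy_sample.ddg
        assert rev.mutations[0].wt_aa == toy_sample.mutations[0].mut_aa

    def test_type_mismatch_rejected(self, toy_sample):
        bad = MutationSpec("W", toy_sample.mutations[0].chain_id,
                           toy_sample.mutations[0].resseq, "Y")
        if toy_sample.wt.residues[
                toy_sample.wt.find(bad.chain_id, bad.resseq)].aa == "W":
            pytest.skip("fixture site happens to be W")
        with pytest.raises(ValueError):
            SampleRecord(toy_sample.wt, toy_sample.mut, [bad], 0.0)
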