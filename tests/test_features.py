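"""Node/pair features: frames, local geometry, distances, embeddings."""

import numpy as np
import pytest

from igmi import (MutationSpec, ToySpec, build_local_frame, contact_map,
                  local_atom_geometry, make_toy_complex, mock_embeddings,
                  pairwise_distances, select_residues, sequence_separation)
from igmi.config import ModelConfig
from igmi.constants import HEAVY_ATOMS
from igmi.features import (MockEmbeddingProvider, PAD_DISTANCE,
                           build_node_features, build_pair_features,
                           featurize_pathway, positional_encoding)
from igmi.structure import AtomRecord, ResidueRecord

from conftest import rigid_motion


def _selection(structure, n_max=128):
    res = structure.residues[0]
    spec = MutationSpec(res.aa, res.chain_id, res.resseq,
                       "A" if res.aa != "A" else "G")
    return spec, select_residues(structure, [spec], n_max=n_max)


class TestLocalFrame:
    def test_axis_aligned_backbone_gives_identity(self):
        res = ResidueRecord("A", 1, "", "G", [
            AtomRecord("CA", "C", np.zeros(3)),
            AtomRecord("C", "C", np.array([1.5, 0.0, 0.0])),
            AtomRecord("N", "N", np.array([-0.5, 1.4, 0.0]))])
        fr = build_local_frame(res)
        np.testing.assert_allclose(fr.R, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(fr.origin, np.zeros(3))

    def test_equivariance_under_rigid_motion(self, toy_complex):
        moved = rigid_motion(toy_complex, seed=2)
        for i in (0, 7, 25):
            f0 = build_local_frame(toy_complex.residues[i])
            f1 = build_local_frame(moved.residues[i])
            # R' R0^T must be the same rotation for every residue
            if i == 0:
                q = f1.R @ f0.R.T
            np.testing.assert_allclose(f1.R @ f0.R.T, q, atol=1e-6)

    def test_collinear_backbone_rejected(self):
        res = ResidueRecord("A", 1, "", "G", [
            AtomRecord("N", "N", np.array([0.0, 0, 0])),
            AtomRecord("CA", "C", np.array([1.0, 0, 0])),
            AtomRecord("C", "C", np.array([2.0, 0, 0]))])
        with pytest.raises(ValueError, match="degenerate"):
            build_local_frame(res)


class TestLocalAtomGeometry:
    def test_ca_slot_is_origin_with_flag(self, toy_complex):
        res = toy_complex.residues[0]
        vec = local_atom_geometry(res, build_local_frame(res))
        coords, flags = vec[:42].reshape(14, 3), vec[42:]
        np.testing.assert_allclose(coords[1], 0.0, atol=1e-9)  # CA slot
        assert flags[1] == 1.0

    def test_invariance_under_rigid_motion(self, toy_complex):
        moved = rigid_motion(toy_complex, seed=9)
        for i in (0, 13, 31):
            a = local_atom_geometry(toy_complex.residues[i],
                                    build_local_frame(toy_complex.residues[i]))
            b = local_atom_geometry(moved.residues[i],
                                    build_local_frame(moved.residues[i]))
            np.testing.assert_allclose(a, b, atol=1e-6)

    @pytest.mark.parametrize("aa,count", [("A", 5), ("G", 4), ("W", 14)])
    def test_presence_flags_match_atom_counts(self, aa, count):
        """The toy generator stores backbone + Cβ; flag count equals the
        stored atoms, and a full side chain would use len(HEAVY_ATOMS)."""
        assert len(HEAVY_ATOMS[aa]) == count or aa in ("A", "G")
        # alanine from the table: exactly 5 heavy-atom slots named
        assert len(HEAVY_ATOMS["A"]) == 5


class TestPairFeatures:
    def test_distances_match_brute_force(self, toy_complex):
        _, sel = _selection(toy_complex, n_max=32)
        D = pairwise_distances(toy_complex, sel)
        from igmi import get_cbeta
        for i in range(0, 30, 7):
            for j in range(0, 30, 5):
                expect = np.linalg.norm(
                    get_cbeta(toy_complex.residues[sel.indices[i]])
                    - get_cbeta(toy_complex.residues[sel.indices[j]]))
                assert D[i, j] == pytest.approx(expect, abs=1e-6)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D)[sel.mask], 0.0)

    def test_padding_rows_carry_sentinel(self, toy_complex):
        _, sel = _selection(toy_complex, n_max=64)
        D = pairwise_distances(toy_complex, sel)
        assert (D[~sel.mask] == PAD_DISTANCE).all()

    def test_contact_map_threshold_closed(self):
        D = np.array([[0.0, 8.0], [8.0, 0.0]])
        c = contact_map(D, threshold=8.0)
        assert c[0, 1] == 1 and c[1, 0] == 1
        assert c[0, 0] == 0  # diagonal excluded
        with pytest.raises(ValueError):
            contact_map(D, threshold=0.0)

    def test_contact_row_sums_match_neighbor_counts(self, toy_complex):
        _, sel = _selection(toy_complex, n_max=40)
        D = pairwise_distances(toy_complex, sel)
        c = contact_map(D, 8.0)
        brute = [(np.delete(D[i], i) <= 8.0).sum() for i in range(40)]
        np.testing.assert_array_equal(c.sum(axis=1), brute)

    def test_sequence_separation(self, toy_complex):
        _, sel = _selection(toy_complex, n_max=40)
        ss = sequence_separation(toy_complex, sel, clip=32)
        # adjacent residues on one chain
        assert ss[0, 1] == 1 and ss[1, 0] == -1
        # cross-chain sentinel
        chains = [toy_complex.residues[i].chain_id for i in sel.indices]
        i = chains.index("A")
        j = chains.index("B")
        assert ss[i, j] == 33
        # antisymmetry within chains
        same = np.array([[a == b for b in chains] for a in chains])
        np.testing.assert_array_equal(ss[same & ~np.eye(40, dtype=bool)],
                                      -ss.T[same & ~np.eye(40, dtype=bool)])

    def test_separation_clipping(self):
        st = make_toy_complex(ToySpec(n_per_chain=40, seed=1))
        res = st.residues[0]
        spec = MutationSpec(res.aa, res.chain_id, res.resseq,
                            "A" if res.aa != "A" else "G")
        sel = select_residues(st, [spec], n_max=80)
        ss = sequence_separation(st, sel, clip=32)
        assert ss.max() == 33 and ss.min() == -32  # clipped at ±32


class TestEmbeddings:
    def test_deterministic(self):
        a = mock_embeddings(["ACDE"], seed=3, embed_dim=8)
        b = mock_embeddings(["ACDE"], seed=3, embed_dim=8)
        np.testing.assert_array_equal(a[0], b[0])

    def test_locality_of_the_mock(self):
        a = mock_embeddings(["AAA"], seed=0)[0]
        b = mock_embeddings(["AAC"], seed=0)[0]
        np.testing.assert_array_equal(a[:2], b[:2])
        assert not np.array_equal(a[2], b[2])

    def test_shapes_and_unit_variance(self):
        out = mock_embeddings(["ACDEFGHIKL", ""], seed=1, embed_dim=32)
        assert out[0].shape == (10, 32)
        assert out[1].shape == (0, 32)
        assert out[0].std() == pytest.approx(1.0, abs=0.15)


class TestEndToEndInvariance:
    def test_features_invariant_under_20_rigid_motions(self, toy_complex):
        cfg = ModelConfig.tiny(dtype="float64")
        provider = MockEmbeddingProvider(seed=0, embed_dim=cfg.embed_dim)
        spec, sel = _selection(toy_complex, n_max=32)
        ref_node = build_node_features(toy_complex, sel, provider, cfg)
        ref_pair = build_pair_features(toy_complex, sel, cfg)
        for seed in range(20):
            moved = rigid_motion(toy_complex, seed=seed)
            node = build_node_features(moved, sel, provider, cfg)
            pair = build_pair_features(moved, sel, cfg)
            np.testing.assert_allclose(node.concat, ref_node.concat, atol=1e-5)
            np.testing.assert_allclose(pair.D, ref_pair.D, atol=1e-5)
            np.testing.assert_array_equal(pair.contact, ref_pair.contact)
            np.testing.assert_array_equal(pair.seqsep, ref_pair.seqsep)

    def test_all_features_finite_including_glycine_rich(self):
        rng_seq_seed = 17
        st = make_toy_complex(ToySpec(n_per_chain=10, seed=rng_seq_seed))
        # force a glycine-rich chain (virtual Cβ path)
        for r in st.residues[:10]:
            r.aa = "G"
            r.atoms = [a for a in r.atoms if a.name != "CB"]
        cfg = ModelConfig.tiny()
        res = st.residues[0]
        spec = MutationSpec("G", res.chain_id, res.resseq, "A")
        sel = select_residues(st, [spec], n_max=32)
        pf = featurize_pathway(st, sel, MockEmbeddingProvider(0, cfg.embed_dim), cfg)
        for name in ("node", "rbf", "anchors", "frames_R", "origins"):
            assert np.isfinite(getattr(pf, name)).all()


def test_positional_encoding_shape_and_range():
    pe = positional_encoding(np.arange(5), dim=16)
    assert pe.shape == (5, 16)
    assert np.abs(pe).max() <= 1.0 + 1e-12
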