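"""Dual-pathway assembly and the antisymmetric prediction head."""

import numpy as np
import pytest

from igmi import IGMIModel, SampleRecord, residue_ddg
from igmi.config import ModelConfig
from igmi.predictor import init_head_params, residue_ddg_core
from igmi import _autodiff as ad

from conftest import moved_sample

RNG = np.random.default_rng(3)


def _head(seed=0, d=32):
    cfg = ModelConfig.tiny(dtype="float64")
    return init_head_params(cfg, np.random.default_rng(seed))


class TestResidueDdg:
    def test_equal_encodings_give_exact_zero(self):
        head = _head()
        u = RNG.standard_normal(32)
        assert residue_ddg(u, u, head) == 0.0

    def test_antisymmetry_over_100_random_pairs(self):
        head = _head(1)
        worst = 0.0
        for _ in range(100):
            a, b = RNG.standard_normal(32), RNG.standard_normal(32)
            worst = max(worst, abs(residue_ddg(a, b, head)
                                   + residue_ddg(b, a, head)))
        assert worst <= 1e-6

    def test_matches_scalar_formula_reference(self):
        """Independent evaluation of the head formula: ReLU chain on both
        concatenation orders, difference times the output map."""
        head = _head(2)
        a, b = RNG.standard_normal(32), RNG.standard_normal(32)

        def ffn(x):
            h = np.maximum(x @ head.W1.data + head.b1.data, 0)
            h = np.maximum(h @ head.W2.data + head.b2.data, 0)
            return np.maximum(h @ head.W3.data + head.b3.data, 0)

        expected = ((ffn(np.concatenate([a, b]))
                     - ffn(np.concatenate([b, a]))) @ head.W_ddg.data)[0]
        assert residue_ddg(a, b, head) == pytest.approx(expected, abs=1e-6)


class TestPredict:
    def test_identical_structures_predict_zero(self, tiny_model, toy_sample):
        noop = SampleRecord.__new__(SampleRecord)  # invariant check only
        noop.wt = toy_sample.wt
        noop.mut = toy_sample.wt
        noop.mutations = toy_sample.mutations
        noop.ddg = 0.0
        assert abs(tiny_model.predict_ddg(noop)) <= 1e-6

    def test_swap_negates_prediction(self, tiny_model, small_dataset):
        for s in small_dataset:
            p = tiny_model.predict_ddg(s)
            q = tiny_model.predict_ddg(s.reversed())
            assert p + q == pytest.approx(0.0, abs=1e-5)

    def test_antisymmetry_holds_at_random_init(self, small_dataset):
        """Architectural, not learned: random untrained weights."""
        for seed in range(5):
            m = IGMIModel(ModelConfig.tiny(), seed=seed)
            s = small_dataset[seed % len(small_dataset)]
            assert m.predict_ddg(s) + m.predict_ddg(s.reversed()) == \
                pytest.approx(0.0, abs=1e-5)

    def test_contributions_sum_to_total_and_negate(self, tiny_model,
                                                   toy_sample):
        sel, contrib = tiny_model.per_residue_contributions(toy_sample)
        total = tiny_model.predict_ddg(toy_sample)
        assert contrib.sum() == pytest.approx(total, abs=1e-5)
        sel_r, contrib_r = tiny_model.per_residue_contributions(
            toy_sample.reversed())
        np.testing.assert_allclose(contrib_r, -contrib, atol=1e-6)

    def test_rigid_motion_invariance(self, tiny_model, toy_sample):
        base = tiny_model.predict_ddg(toy_sample)
        for seed in range(5):
            moved = moved_sample(toy_sample, seed)
            assert tiny_model.predict_ddg(moved) == \
                pytest.approx(base, abs=1e-3)


class TestEncoderProperties:
    def test_output_shape_follows_d_model(self, tiny_model, toy_sample):
        sf = tiny_model.featurize(toy_sample)
        from igmi.predictor import stack_pathways
        u, A, P = tiny_model.encode_batch(stack_pathways([sf.wt]))
        assert u.data.shape == (1, 32, 32)  # (batch, Nres, d_model)
        assert A.data.shape == (1, 2, 32, 32)

    def test_blocks_do_not_share_parameters(self, toy_sample):
        """Perturbing only the second block's weights changes the output."""
        m = IGMIModel(ModelConfig.tiny(), seed=0)
        base = m.predict_ddg(toy_sample)
        m.encoder.blocks[1].ffn_W1.data = \
            m.encoder.blocks[1].ffn_W1.data + 0.5
        assert m.predict_ddg(toy_sample) != pytest.approx(base, abs=1e-9)

    def test_frozen_gates_match_baseline_combination(self, tiny_model,
                                                     toy_sample):
        """Gates pinned at (1, σ→1, 1) reproduce the plain α1-α2+α3 model."""
        from igmi.predictor import stack_pathways
        sf = tiny_model.featurize(toy_sample)
        batch = stack_pathways([sf.wt, sf.mut])
        u_frozen, _, _ = tiny_model.encode_batch(
            batch, gate_override=(1.0, 1.0, 1.0))
        u_base, _, _ = tiny_model.encode_batch(batch, use_proteomae=False)
        np.testing.assert_allclose(u_frozen.data, u_base.data, atol=1e-6)


class TestFullSizeConfiguration:
    def test_default_width_encoding_and_padded_prediction(self, toy_sample):
        """Default architecture: u is (Nres, 128); a 40-residue complex in
        a 128-slot subgraph exercises the padding path end to end."""
        model = IGMIModel(ModelConfig(), seed=0)
        sf = model.featurize(toy_sample)
        assert sf.selection.n_valid == 40
        from igmi.predictor import stack_pathways
        u, A, P = model.encode_batch(stack_pathways([sf.wt]))
        assert u.data.shape == (1, 128, 128)
        # padding rows of u are zero; padding keys receive no attention
        np.testing.assert_allclose(u.data[0, ~sf.selection.mask], 0.0)
        assert np.all(P.data[0][:, :, ~sf.selection.mask] == 0)
        p = model.predict_ddg(toy_sample)
        q = model.predict_ddg(toy_sample.reversed())
        assert np.isfinite(p)
        assert p + q == pytest.approx(0.0, abs=1e-5)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, toy_sample):
        m = IGMIModel(ModelConfig.tiny(), seed=4)
        before = m.predict_ddg(toy_sample)
        m.save(tmp_path / "ckpt")
        m2 = IGMIModel.load(tmp_path / "ckpt")
        assert m2.predict_ddg(toy_sample) == pytest.approx(before, abs=1e-6)
        assert m2.config == m.config

    def test_shape_mismatch_detected(self, tmp_path):
        m = IGMIModel(ModelConfig.tiny(), seed=0)
        m.save(tmp_path / "ckpt")
        import json
        manifest = json.loads((tmp_path / "ckpt.json").read_text())
        manifest["config"]["d_model"] = 64
        (tmp_path / "ckpt.json").write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="mismatch"):
            IGMIModel.load(tmp_path / "ckpt")
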