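"""Channel biases, squeeze/fuse/gate/recalibrate, and attention blocks.

All functional ops run in float64 here and are checked against independent
brute-force implementations written directly from their definitions.
"""

import numpy as np
import pytest

from igmi import _autodiff as ad
from igmi.config import ModelConfig
from igmi.encoder import (BlockParams, ChannelBiasParams, FusionParams,
                          GateParams, attention_block, channel_biases,
                          combine_channels, fuse, gate, init_encoder_params,
                          recalibrate, squeeze)

RNG = np.random.default_rng(42)


def _channel_params(K=16, H=2, V=66, e=4) -> ChannelBiasParams:
    t = lambda s: ad.Tensor(RNG.standard_normal(s), requires_grad=False)
    return ChannelBiasParams(rbf_w=t((K, H)), contact_emb=t((2, H)),
                             seqsep_emb=t((V, e)), pairtype_emb=t((400, e)),
                             pair_w=t((2 * e, H)))


def _fusion_params(Hz=2, N=6, Dkz=4) -> FusionParams:
    t = lambda s: ad.Tensor(RNG.standard_normal(s), requires_grad=False)
    return FusionParams(Wq=t((Hz, N, Dkz)), Wk=t((Hz, N, Dkz)),
                        Wv=t((Hz, N, Dkz)))


def _gate_params(F=8, N=6) -> GateParams:
    t = lambda s: ad.Tensor(RNG.standard_normal(s), requires_grad=False)
    return GateParams(W1=t((F, N)), W2=t((N, 1)))


class TestChannelBiases:
    def _inputs(self, n=10, K=16):
        rbf = RNG.random((n, n, K))
        contact = RNG.integers(0, 2, (n, n))
        seqsep = RNG.integers(0, 66, (n, n))
        pairtype = RNG.integers(0, 400, (n, n))
        return rbf, contact, seqsep, pairtype

    def test_identical_pair_descriptors_give_identical_entries(self):
        rbf, contact, seqsep, pairtype = self._inputs()
        rbf[3, 4] = rbf[7, 2]
        contact[3, 4] = contact[7, 2]
        seqsep[3, 4] = seqsep[7, 2]
        pairtype[3, 4] = pairtype[7, 2]
        p = _channel_params()
        a = channel_biases(rbf, contact, seqsep, pairtype, p)
        np.testing.assert_allclose(a[:, :, 3, 4], a[:, :, 7, 2], atol=1e-12)

    def test_padding_pairs_are_zero(self):
        rbf, contact, seqsep, pairtype = self._inputs()
        mask = np.ones(10, dtype=bool)
        mask[7:] = False
        rbf[7:] = 0.0
        rbf[:, 7:] = 0.0
        a = channel_biases(rbf, contact, seqsep, pairtype, _channel_params(),
                           mask=mask)
        assert np.all(a[:, :, 7:, :] == 0) and np.all(a[:, :, :, 7:] == 0)

    def test_permutation_equivariance(self):
        rbf, contact, seqsep, pairtype = self._inputs()
        p = _channel_params()
        a = channel_biases(rbf, contact, seqsep, pairtype, p)
        perm = RNG.permutation(10)
        b = channel_biases(rbf[np.ix_(perm, perm)], contact[np.ix_(perm, perm)],
                           seqsep[np.ix_(perm, perm)],
                           pairtype[np.ix_(perm, perm)], p)
        np.testing.assert_allclose(b, a[:, :, perm][:, :, :, perm], atol=1e-12)


class TestSqueeze:
    def test_hand_computed_all_ones(self):
        """alpha all ones with N=4, H=2 → every z entry is 4*2 = 8."""
        alpha = np.ones((3, 2, 4, 4))
        np.testing.assert_allclose(squeeze(alpha), np.full((3, 4), 8.0))

    def test_zero_channels_give_zero(self):
        assert np.all(squeeze(np.zeros((3, 2, 5, 5))) == 0)

    def test_matches_triple_loop(self):
        alpha = RNG.standard_normal((3, 2, 5, 5))
        z = squeeze(alpha)
        for c in range(3):
            for j in range(5):
                brute = sum(alpha[c, h, i, j]
                            for h in range(2) for i in range(5))
                assert z[c, j] == pytest.approx(brute, abs=1e-6)


class TestFuse:
    def test_rows_are_convex_mixtures(self):
        """Each channel token's output is a softmax mixture, so the fused
        output of identical tokens is identical."""
        z = np.repeat(RNG.standard_normal((1, 6)), 3, axis=0)
        p = _fusion_params()
        out = fuse(z, p)
        np.testing.assert_allclose(out[0], out[1], atol=1e-10)

    def test_single_token_identity(self):
        """C=1: the 1x1 softmax is exactly 1, so output = z Wv (per head)."""
        z = RNG.standard_normal((1, 6))
        p = _fusion_params()
        out = fuse(z, p)
        expected = np.concatenate([z @ p.Wv.data[h] for h in range(2)],
                                  axis=-1)[0]
        np.testing.assert_allclose(out[0], expected, atol=1e-10)

    def test_matches_dense_reference(self):
        """Explicit per-head computation on a C=3, N=6, Hz=2, Dkz=4 case."""
        z = RNG.standard_normal((3, 6))
        p = _fusion_params()
        out = fuse(z, p)
        heads = []
        for h in range(2):
            q = z @ p.Wq.data[h]
            k = z @ p.Wk.data[h]
            v = z @ p.Wv.data[h]
            logits = q @ k.T / np.sqrt(4.0)
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            att = e / e.sum(axis=1, keepdims=True)
            assert np.allclose(att.sum(axis=1), 1.0, atol=1e-6)
            heads.append(att @ v)
        np.testing.assert_allclose(out, np.concatenate(heads, axis=-1),
                                   atol=1e-6)


class TestGate:
    def test_zero_weights_closed_form(self):
        """All-zero gate weights → s_c = softplus(0) = ln 2."""
        p = GateParams(W1=ad.Tensor(np.zeros((8, 6))),
                       W2=ad.Tensor(np.zeros((6, 1))))
        out = gate(RNG.standard_normal((3, 8)), p)
        np.testing.assert_allclose(out, np.log(2.0), atol=1e-9)

    def test_strict_positivity_over_1000_draws(self):
        vals = []
        for _ in range(1000):
            p = _gate_params()
            vals.append(gate(RNG.standard_normal((3, 8)), p))
        assert np.min(vals) > 0.0

    def test_monotone_in_pre_softplus_scalar(self):
        p = GateParams(W1=ad.Tensor(np.ones((1, 1))),
                       W2=ad.Tensor(np.ones((1, 1))))
        xs = np.array([[0.1], [0.5], [2.0]])
        outs = [gate(x[None, :], p)[0] for x in xs]
        assert outs[0] < outs[1] < outs[2]


class TestRecalibrate:
    def test_large_s2_recovers_baseline_combination(self):
        """s = (1, 40, 1): sigmoid(40) ≈ 1, so A ≈ α1 - α2 + α3."""
        channels = RNG.standard_normal((3, 2, 5, 5))
        A = recalibrate(channels, np.array([1.0, 40.0, 1.0]))
        np.testing.assert_allclose(A, combine_channels(channels), atol=1e-6)

    def test_scalar_hand_example(self):
        """α = (2, 3, 5), s = (2, 0, 1): A = 2*2 - 0.5*3 + 1*5 = 7.5."""
        channels = np.array([2.0, 3.0, 5.0]).reshape(3, 1, 1, 1)
        A = recalibrate(channels, np.array([2.0, 0.0, 1.0]))
        assert A[0, 0, 0] == pytest.approx(7.5, abs=1e-9)

    def test_contact_coefficient_bounded(self):
        """The α2 coefficient is sigmoid(s2) ∈ (0, 1); α1/α3 keep s > 0."""
        for _ in range(50):
            s = np.abs(RNG.standard_normal(3)) + 1e-3
            a2 = np.zeros((3, 1, 1, 1))
            a2[1] = 1.0
            coeff = -recalibrate(a2, s)[0, 0, 0]
            assert 0.0 < coeff < 1.0

    def test_padding_keys_masked_to_minus_inf(self):
        channels = RNG.standard_normal((3, 2, 4, 4))
        mask = np.array([True, True, False, False])
        A = recalibrate(channels, np.array([1.0, 1.0, 1.0]), mask=mask)
        assert np.isneginf(A[:, :, 2:]).all()
        assert np.isfinite(A[:, :, :2]).all()


def _block_params(cfg: ModelConfig, seed=0) -> BlockParams:
    return init_encoder_params(cfg, np.random.default_rng(seed)).blocks[0]


class TestAttentionBlock:
    CFG = ModelConfig.tiny(dtype="float64")

    def test_zero_bias_gives_uniform_attention(self):
        """A = 0: every query averages the same value vectors, so all rows
        of the output are identical."""
        p = _block_params(self.CFG)
        nodes = np.repeat(RNG.standard_normal((1, 32)), 4, axis=0)
        nodes = np.concatenate([nodes, RNG.standard_normal((0, 32))])
        out = attention_block(np.tile(RNG.standard_normal(32), (4, 1)),
                              np.zeros((2, 4, 4)), p,
                              mask=np.ones(4, dtype=bool))
        np.testing.assert_allclose(out[0], out[1], atol=1e-9)

    def test_padding_keys_receive_zero_attention(self):
        from igmi.encoder import attention_weights
        mask = np.array([True, True, True, False])
        A = ad.Tensor(RNG.standard_normal((2, 4, 4)))
        P = attention_weights(A, mask).data
        assert np.all(P[:, :, 3] == 0)
        np.testing.assert_allclose(P[:, :3].sum(axis=-1), 1.0, atol=1e-9)

    def test_matches_loop_reference(self):
        """Block output equals an explicit per-head loop implementation."""
        cfg = self.CFG
        p = _block_params(cfg, seed=3)
        n, d, H = 6, cfg.d_model, cfg.H
        nodes = RNG.standard_normal((n, d))
        A = RNG.standard_normal((H, n, n))
        out = attention_block(nodes, A, p, mask=np.ones(n, dtype=bool))

        # reference: pre-LN attention + FFN with residuals
        def ln(x, g, b):
            mu = x.mean(-1, keepdims=True)
            sd = np.sqrt(((x - mu) ** 2).mean(-1, keepdims=True) + 1e-5)
            return (x - mu) / sd * g + b

        xin = ln(nodes, p.ln1_g.data, p.ln1_b.data)
        v = xin @ p.attn_Wv.data
        dv = d // H
        ctx = np.zeros((n, d))
        for h in range(H):
            e = np.exp(A[h] - A[h].max(axis=1, keepdims=True))
            P = e / e.sum(axis=1, keepdims=True)
            ctx[:, h * dv:(h + 1) * dv] = P @ v[:, h * dv:(h + 1) * dv]
        x = nodes + ctx @ p.attn_Wo.data
        hmid = np.maximum(ln(x, p.ln2_g.data, p.ln2_b.data) @ p.ffn_W1.data
                          + p.ffn_b1.data, 0.0)
        ref = x + hmid @ p.ffn_W2.data + p.ffn_b2.data
        np.testing.assert_allclose(out, ref, atol=1e-5)
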