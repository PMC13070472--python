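"""Biased graph attention over residue subgraphs with channel recalibration.

Three pairwise bias channels are built per attention head:

* ``α1`` — 3D structure: a per-head linear map of a Gaussian radial-basis
  expansion of the Cβ-Cβ distance;
* ``α2`` — 2D contacts: a learned per-head scalar embedding of the binary
  contact indicator;
* ``α3`` — 1D sequence: a per-head linear map of the concatenated
  sequence-separation and residue-pair-type embeddings.

The baseline combination ``A = α1 - α2 + α3`` is the attention logit of
every head.  The channel-recalibration unit (ProteoMAE) replaces the fixed
combination with gated coefficients: each channel is squeezed to a
per-residue descriptor, the three descriptors are mixed by a small
multi-head self-attention, and a positive gate per channel rescales its
contribution — the contact channel through a sigmoid so its (subtracted)
coefficient stays in (0, 1).  Freezing the gates at (1, 1, 1) recovers the
baseline combination exactly, which is how the ablation variants are wired.

Attention logits are the bias itself (no content query/key term): the
multidimensional encodings *are* the attention.  Each block applies masked
multi-head attention to the residue states followed by a feed-forward
sublayer, both with residual connections; blocks do not share parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .config import ModelConfig

__all__ = [
    "ChannelBiasParams",
    "FusionParams",
    "GateParams",
    "BlockParams",
    "EncoderParams",
    "init_encoder_params",
    "channel_biases",
    "squeeze",
    "fuse",
    "gate",
    "recalibrate",
    "attention_block",
    "attention_weights",
    "combine_channels",
]


# -- parameter containers --------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            dtype=np.float64) -> Tensor:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[-1], shape[-1]
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return Tensor((rng.standard_normal(shape) * std).astype(dtype),
                  requires_grad=True)


def _zeros(shape, dtype=np.float64) -> Tensor:
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


@dataclass
class ChannelBiasParams:
    """Learned maps from pair descriptors to per-head biases."""

    rbf_w: Tensor        # (K, H)
    contact_emb: Tensor  # (2, H)
    seqsep_emb: Tensor   # (V_seqsep, e)
    pairtype_emb: Tensor # (400, e)
    pair_w: Tensor       # (2e, H)

    def tensors(self) -> list[Tensor]:
        return [self.rbf_w, self.contact_emb, self.seqsep_emb,
                self.pairtype_emb, self.pair_w]


@dataclass
class FusionParams:
    """Multi-head self-attention over the three channel descriptors."""

    Wq: Tensor  # (Hz, N, Dkz)
    Wk: Tensor  # (Hz, N, Dkz)
    Wv: Tensor  # (Hz, N, Dkz)

    def tensors(self) -> list[Tensor]:
        return [self.Wq, self.Wk, self.Wv]


@dataclass
class GateParams:
    """Two-layer gating network producing strictly positive channel gates."""

    W1: Tensor  # (Hz*Dkz, N)
    W2: Tensor  # (N, 1)

    def tensors(self) -> list[Tensor]:
        return [self.W1, self.W2]


@dataclass
class BlockParams:
    channel: ChannelBiasParams
    fusion: FusionParams
    gate: GateParams
    attn_Wv: Tensor
    attn_Wo: Tensor
    ffn_W1: Tensor
    ffn_b1: Tensor
    ffn_W2: Tensor
    ffn_b2: Tensor
    ln1_g: Tensor
    ln1_b: Tensor
    ln2_g: Tensor
    ln2_b: Tensor
    bsa_add_W: Tensor | None = None  # only in bsa_mode="add"

    def tensors(self) -> list[Tensor]:
        out = (self.channel.tensors() + self.fusion.tensors()
               + self.gate.tensors()
               + [self.attn_Wv, self.attn_Wo,
                  self.ffn_W1, self.ffn_b1, self.ffn_W2, self.ffn_b2,
                  self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b])
        if self.bsa_add_W is not None:
            out.append(self.bsa_add_W)
        return out


@dataclass
class EncoderParams:
    node_W1: Tensor
    node_b1: Tensor
    node_W2: Tensor
    node_b2: Tensor
    blocks: list[BlockParams] = field(default_factory=list)
    out_W: Tensor | None = None  # ((d [+7H]) x d) final projection to u
    out_b: Tensor | None = None
    lnf_g: Tensor | None = None  # final pre-projection layer norm
    lnf_b: Tensor | None = None

    def tensors(self) -> list[Tensor]:
        out = [self.node_W1, self.node_b1, self.node_W2, self.node_b2]
        for b in self.blocks:
            out.extend(b.tensors())
        if self.out_W is not None:
            out.extend([self.out_W, self.out_b])
        if self.lnf_g is not None:
            out.extend([self.lnf_g, self.lnf_b])
        return out


def init_encoder_params(cfg: ModelConfig, rng: np.random.Generator) -> EncoderParams:
    dt = np.float32 if cfg.dtype == "float32" else np.float64
    e = cfg.pair_embed_dim
    # locality prior: with Gaussian RBF activations that are near one-hot in
    # the distance, a weight profile -center*locality_init makes the initial
    # 3D-channel logit ≈ -locality_init * distance
    centers = np.linspace(0.0, cfg.rbf_max, cfg.rbf_bins)
    locality = np.repeat(
        (-cfg.locality_init * centers)[:, None], cfg.H, axis=1).astype(dt)
    bs = cfg.bias_init_scale
    blocks = []
    for _ in range(cfg.n_blocks):
        rbf_w = _glorot(rng, (cfg.rbf_bins, cfg.H), dt)
        rbf_w.data = rbf_w.data * bs + locality
        contact_emb = _glorot(rng, (2, cfg.H), dt)
        contact_emb.data = contact_emb.data * bs
        pair_w = _glorot(rng, (2 * e, cfg.H), dt)
        pair_w.data = pair_w.data * bs
        seqsep_emb = _glorot(rng, (cfg.seqsep_vocab, e), dt)
        if cfg.cross_init:
            # factorized boost: sentinel row x first embedding coordinate,
            # routed to the last head (A3 enters A with +sign)
            cross_head = cfg.H - 1
            seqsep_emb.data[cfg.seqsep_vocab - 1, 0] += 1.0
            pair_w.data[0, cross_head] += dt(cfg.cross_init)
        channel = ChannelBiasParams(
            rbf_w=rbf_w,
            contact_emb=contact_emb,
            seqsep_emb=seqsep_emb,
            pairtype_emb=_glorot(rng, (400, e), dt),
            pair_w=pair_w,
        )
        fusion = FusionParams(
            Wq=_glorot(rng, (cfg.Hz, cfg.n_max, cfg.Dkz), dt),
            Wk=_glorot(rng, (cfg.Hz, cfg.n_max, cfg.Dkz), dt),
            Wv=_glorot(rng, (cfg.Hz, cfg.n_max, cfg.Dkz), dt),
        )
        # W2 starts at zero so every gate begins at softplus(0) = ln 2
        # regardless of the scale of the raw squeeze descriptors; otherwise
        # the unbounded softplus amplifies the bias channels at init and
        # saturates the attention softmax
        gatep = GateParams(
            W1=_glorot(rng, (cfg.Hz * cfg.Dkz, cfg.n_max), dt),
            W2=_zeros((cfg.n_max, 1), dt),
        )
        d, m = cfg.d_model, cfg.ffn_mult
        blocks.append(BlockParams(
            channel=channel, fusion=fusion, gate=gatep,
            attn_Wv=_glorot(rng, (d, d), dt),
            attn_Wo=_glorot(rng, (d, d), dt),
            ffn_W1=_glorot(rng, (d, m * d), dt),
            ffn_b1=_zeros((m * d,), dt),
            ffn_W2=_glorot(rng, (m * d, d), dt),
            ffn_b2=_zeros((d,), dt),
            ln1_g=Tensor(np.ones(d, dtype=dt), requires_grad=True),
            ln1_b=_zeros((d,), dt),
            ln2_g=Tensor(np.ones(d, dtype=dt), requires_grad=True),
            ln2_b=_zeros((d,), dt),
            bsa_add_W=(_glorot(rng, (7 * cfg.H, d), dt)
                       if (cfg.use_bsa and cfg.bsa_mode == "add") else None),
        ))
    d = cfg.d_model
    u_in = d + (7 * cfg.H if (cfg.use_bsa and cfg.bsa_mode == "concat") else 0)
    return EncoderParams(
        node_W1=_glorot(rng, (cfg.node_feature_dim, d), dt),
        node_b1=_zeros((d,), dt),
        node_W2=_glorot(rng, (d, d), dt),
        node_b2=_zeros((d,), dt),
        blocks=blocks,
        out_W=_glorot(rng, (u_in, d), dt),
        out_b=_zeros((d,), dt),
        lnf_g=Tensor(np.ones(d, dtype=dt), requires_grad=True),
        lnf_b=_zeros((d,), dt),
    )


# -- core operations (Tensor in / Tensor out, batched) ---------------------

def channel_biases_core(rbf, contact_idx, seqsep_idx, pairtype_idx,
                        pair_mask: np.ndarray,
                        p: ChannelBiasParams) -> list[Tensor]:
    """The three per-head bias channels [α1, α2, α3], padding pairs zeroed.

    Input arrays have shape (..., N, N[, K]); outputs are (..., H, N, N).
    """
    rbf = ad.as_tensor(rbf)
    pm = np.asarray(pair_mask, dtype=rbf.data.dtype)
    # α1: the radial-basis row of a padding pair is exactly zero (the
    # sentinel distance underflows every Gaussian), so no mask is needed.
    a1 = ad.matmul(rbf, p.rbf_w)                            # (..., N, N, H)
    a2 = ad.take(p.contact_emb, np.asarray(contact_idx))    # (..., N, N, H)
    # α3 = (seqsep_emb ⊕ pairtype_emb) @ pair_w, evaluated as two small
    # per-vocabulary tables (embedding @ weight-slab) gathered per pair —
    # algebraically identical, but avoids materializing (..., N, N, 2e).
    e = p.seqsep_emb.data.shape[1]
    t_seq = ad.matmul(p.seqsep_emb, p.pair_w[:e])           # (V_seq, H)
    t_pt = ad.matmul(p.pairtype_emb, p.pair_w[e:])          # (400, H)
    a3 = ad.take(t_seq, np.asarray(seqsep_idx)) + ad.take(t_pt, np.asarray(pairtype_idx))
    out = [a1.moveaxis(-1, -3)]
    for a in (a2, a3):
        out.append((a * pm[..., None]).moveaxis(-1, -3))    # (..., H, N, N)
    return out


def squeeze_core(alphas: list[Tensor]) -> Tensor:
    """Channel descriptors z[c, j] = Σ_i Σ_h α_c[h, i, j], shape (..., C, N)."""
    return ad.stack([a.sum(axis=(-3, -2)) for a in alphas], axis=-2)


def pair_tables(p: ChannelBiasParams) -> tuple[Tensor, Tensor]:
    """Per-vocabulary bias tables T_s = E_s W_top, T_p = E_p W_bot.

    Gathering these (V, H) tables per pair is algebraically identical to
    ``(seqsep_emb ⊕ pairtype_emb) @ pair_w`` but never materializes the
    (N, N, 2e) embedding tensor.
    """
    e = p.seqsep_emb.data.shape[1]
    return ad.matmul(p.seqsep_emb, p.pair_w[:e]), ad.matmul(p.pairtype_emb, p.pair_w[e:])


def channel_squeeze_fast(rbf_colsum, contact_n1, contact_n0,
                         seqsep_hist, pairtype_hist,
                         p: ChannelBiasParams, T_s: Tensor, T_p: Tensor
                         ) -> Tensor:
    """z (..., 3, N) from constant per-column aggregates.

    Algebraically identical to ``squeeze_core(channel_biases_core(...))``
    (sums commute with the linear channel maps), but runs on per-residue
    arrays instead of (N, N, H) tensors.
    """
    K = p.rbf_w.data.shape[0]
    w1 = p.rbf_w.sum(axis=-1).reshape((K, 1))
    z1 = ad.matmul(ad.as_tensor(rbf_colsum), w1)[..., 0]
    ce = p.contact_emb.sum(axis=-1)
    z2 = ce[1] * ad.as_tensor(contact_n1) + ce[0] * ad.as_tensor(contact_n0)
    z3 = (ad.matmul(ad.as_tensor(seqsep_hist), T_s.sum(axis=-1, keepdims=True))[..., 0]
          + ad.matmul(ad.as_tensor(pairtype_hist), T_p.sum(axis=-1, keepdims=True))[..., 0])
    return ad.stack([z1, z2, z3], axis=-2)


def fused_combine(g1: Tensor, contact: np.ndarray, comb_idx: np.ndarray,
                  T_comb: Tensor, contact_emb: Tensor,
                  s: Tensor | None,
                  coeffs: tuple[float, float, float] | None = None) -> Tensor:
    """Fused head-first channel combination (Numba kernel + custom VJP).

    Computes A = c1 g1 - c2 g2 + c3 g3 in (B, H, N, N) layout, where g2 is
    the contact-embedding logit and g3 the combined pair-table gather; used
    by the batched model forward.  Equivalence with the explicit
    per-channel construction is covered by tests.
    """
    from . import _kernels
    dt = g1.data.dtype
    B = g1.data.shape[0]
    e0 = np.ascontiguousarray(contact_emb.data[0])
    e1 = np.ascontiguousarray(contact_emb.data[1])
    if coeffs is not None:
        c1 = np.full(B, coeffs[0], dtype=dt)
        c2 = np.full(B, coeffs[1], dtype=dt)
        c3 = np.full(B, coeffs[2], dtype=dt)
        sig2 = None
    else:
        c1 = np.ascontiguousarray(s.data[..., 0])
        raw2 = s.data[..., 1]
        sig2 = 1.0 / (1.0 + np.exp(-np.clip(raw2, -60, 60))).astype(dt)
        c2 = np.ascontiguousarray(sig2.astype(dt))
        c3 = np.ascontiguousarray(s.data[..., 2])
    contact = np.ascontiguousarray(contact, dtype=dt)
    comb_idx = np.ascontiguousarray(comb_idx)
    tcomb = T_comb.data
    A = _kernels.combine_fwd(g1.data, contact, comb_idx, tcomb,
                             e0, e1, c1, c2, c3)
    parents = [g1, T_comb, contact_emb] + ([s] if s is not None else [])

    def backward(g: np.ndarray):
        need_gates = s is not None
        dg1, dtc, de0, de1, dc1, dc2, dc3 = _kernels.combine_bwd(
            np.ascontiguousarray(g), g1.data, contact, comb_idx, tcomb,
            e0, e1, c1, c2, c3, need_gates)
        dce = np.stack([de0, de1])
        if not need_gates:
            return dg1, dtc, dce
        ds = np.stack([dc1, dc2 * sig2 * (1.0 - sig2), dc3], axis=-1)
        return dg1, dtc, dce, ds.astype(dt)

    return ad._op(A, parents, backward)


def fused_attention_softmax(A: Tensor, mask: np.ndarray) -> Tensor:
    """Masked key softmax (B, H, N, N) via the fused kernel."""
    from . import _kernels
    kmask = np.ascontiguousarray(mask, dtype=np.bool_)
    P = _kernels.softmax_fwd(A.data, kmask)

    def backward(g: np.ndarray):
        return (_kernels.softmax_bwd(np.ascontiguousarray(g), P, kmask),)

    return ad._op(P, (A,), backward)


def fuse_core(z: Tensor, p: FusionParams) -> Tensor:
    """Self-attention over the C channel tokens; heads concatenated.

    z: (..., C, N) → (..., C, Hz*Dkz).  The softmax runs over the channel
    axis and is scaled by sqrt(Dkz).
    """
    zq = ad.matmul(z[..., None, :, :], p.Wq)   # (..., Hz, C, Dkz)
    zk = ad.matmul(z[..., None, :, :], p.Wk)
    zv = ad.matmul(z[..., None, :, :], p.Wv)
    dkz = p.Wq.data.shape[-1]
    logits = ad.matmul(zq, zk.moveaxis(-1, -2)) / np.sqrt(float(dkz))
    att = ad.masked_softmax(logits, np.ones(logits.shape, dtype=bool), axis=-1)
    mixed = ad.matmul(att, zv)                 # (..., Hz, C, Dkz)
    mixed = mixed.moveaxis(-3, -2)             # (..., C, Hz, Dkz)
    hz, dk = p.Wq.data.shape[0], dkz
    return mixed.reshape(mixed.shape[:-2] + (hz * dk,))


def gate_core(fused: Tensor, p: GateParams) -> Tensor:
    """Strictly positive channel gates s_c = softplus(relu(f W1) W2)."""
    h = ad.relu(ad.matmul(fused, p.W1))
    s = ad.softplus(ad.matmul(h, p.W2))
    return s[..., 0]                            # (..., C)


def recalibrate_core(alphas: list[Tensor], s: Tensor | None,
                     coeffs: tuple[float, float, float] | None = None) -> Tensor:
    """Combine channels into attention logits A = c1 α1 - c2 α2 + c3 α3.

    With a gate tensor ``s``: c1 = s1, c2 = sigmoid(s2), c3 = s3.  With
    explicit ``coeffs`` the numbers are used verbatim (the frozen-gate
    ablation path).
    """
    a1, a2, a3 = alphas
    if coeffs is not None:
        c1, c2, c3 = (float(c) for c in coeffs)
        return c1 * a1 - c2 * a2 + c3 * a3

    def expand(t: Tensor) -> Tensor:  # (...,) -> (..., 1, 1, 1)
        return t.reshape(t.shape + (1, 1, 1))

    c1 = expand(s[..., 0])
    c2 = expand(ad.sigmoid(s[..., 1]))
    c3 = expand(s[..., 2])
    return c1 * a1 - c2 * a2 + c3 * a3


def attention_weights(A: Tensor, mask: np.ndarray) -> Tensor:
    """Post-softmax attention: row-stochastic over valid keys per head.

    Attention logits are the bias ``A`` itself, so the weights depend only
    on the pair features and channel gates, not on the node states.
    """
    m = np.asarray(mask, dtype=bool)
    return ad.masked_softmax(A, m[..., None, None, :], axis=-1)


def _apply_attention(P: Tensor, v: Tensor, H: int) -> Tensor:
    """ctx[..., i, (h d)] = Σ_j P[..., h, i, j] v[..., j, (h d)].

    One einsum instead of the reshape/transpose/batched-matmul dance; the
    backward pass mirrors it.
    """
    d = v.data.shape[-1]
    dv = d // H
    v4 = v.data.reshape(v.data.shape[:-1] + (H, dv))

    def fwd(Pd, vd):
        return np.einsum("...hij,...jhd->...ihd", Pd, vd,
                         optimize=True)

    out = fwd(P.data, v4)

    def backward(g: np.ndarray):
        g4 = g.reshape(out.shape)
        dP = (np.einsum("...ihd,...jhd->...hij", g4, v4, optimize=True)
              if P.requires_grad else None)
        dv_ = (np.einsum("...hij,...ihd->...jhd", P.data, g4, optimize=True)
               .reshape(v.data.shape) if v.requires_grad else None)
        return dP, dv_

    res = ad._op(out, (P, v), backward)
    return res.reshape(out.shape[:-2] + (d,))


def make_dropout(p: float, rng: np.random.Generator | None,
                 pair_shared: bool = False):
    """Dropout closure; with ``pair_shared`` consecutive batch rows (the
    wild-type/mutant pathways of one sample) share one mask, so the pathway
    *difference* seen by the antisymmetric head is not dropout noise."""
    if rng is None or p <= 0:
        return None

    def drop(t: Tensor) -> Tensor:
        shape = t.data.shape
        if pair_shared and shape[0] % 2 == 0:
            keep = rng.random((shape[0] // 2,) + shape[1:]) >= p
            keep = np.repeat(keep, 2, axis=0)
        else:
            keep = rng.random(shape) >= p
        return t * (keep.astype(t.data.dtype) / (1.0 - p))

    return drop


def attention_block_core(nodes: Tensor, P: Tensor, p: BlockParams,
                         extra: Tensor | None = None,
                         drop=None) -> Tensor:
    """One encoder block: attention (weights ``P``) + FFN, both residual.

    ``P`` is the post-softmax attention (..., H, N, N); ``extra`` (e.g. the
    projected side-chain code) is added to the residue states after the
    attention residual, before the FFN.

    Padding rows are *not* re-zeroed here: attention already masks padding
    keys, every other operation is row-local, and the encoder masks its
    final output, so padding never leaks into valid residues.
    """
    H = P.shape[-3]
    xin = ad.layer_norm(nodes, p.ln1_g, p.ln1_b)    # pre-LN sublayers
    v = ad.matmul(xin, p.attn_Wv)                   # (..., N, d)
    if drop is not None:                            # attention-weight dropout
        P = drop(P)
    ctx = _apply_attention(P, v, H)                 # (..., N, d)
    ctx = ad.matmul(ctx, p.attn_Wo)
    if drop is not None:
        ctx = drop(ctx)
    x = nodes + ctx
    if extra is not None:
        x = x + extra
    h = ad.relu(ad.matmul(ad.layer_norm(x, p.ln2_g, p.ln2_b), p.ffn_W1)
                + p.ffn_b1)
    f = ad.matmul(h, p.ffn_W2) + p.ffn_b2
    if drop is not None:
        f = drop(f)
    return x + f


# -- public functional wrappers (NumPy in / NumPy out) ---------------------

def channel_biases(pair_rbf: np.ndarray, contact: np.ndarray,
                   seqsep_idx: np.ndarray, pairtype_idx: np.ndarray,
                   params: ChannelBiasParams,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Correlation channels as a (3, H, N, N) array (see module docstring)."""
    n = pair_rbf.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    pm = mask[:, None] & mask[None, :]
    alphas = channel_biases_core(pair_rbf, contact.astype(int), seqsep_idx,
                                 pairtype_idx, pm, params)
    return np.stack([a.data for a in alphas])


def squeeze(channels: np.ndarray) -> np.ndarray:
    """z[c, j] = Σ_i Σ_h channels[c, h, i, j]; input (C, H, N, N) → (C, N)."""
    return squeeze_core([ad.as_tensor(c) for c in channels]).data


def fuse(z: np.ndarray, params: FusionParams) -> np.ndarray:
    """Fused channel descriptor, (C, N) → (C, Hz*Dkz)."""
    return fuse_core(ad.as_tensor(z), params).data


def gate(fused: np.ndarray, params: GateParams) -> np.ndarray:
    """Channel gates, (C, F) → (C,); every entry is strictly positive."""
    return gate_core(ad.as_tensor(fused), params).data


def recalibrate(channels: np.ndarray, s: np.ndarray,
                mask: np.ndarray | None = None) -> np.ndarray:
    """Attention bias A = s1 α1 - sigmoid(s2) α2 + s3 α3, (H, N, N).

    Padding keys (mask False) are set to -inf so downstream softmax ignores
    them.
    """
    alphas = [ad.as_tensor(c) for c in channels]
    A = recalibrate_core(alphas, ad.as_tensor(np.asarray(s, dtype=float))).data
    if mask is not None:
        A = np.where(np.asarray(mask, dtype=bool)[None, None, :], A, -np.inf)
    return A


def combine_channels(channels: np.ndarray) -> np.ndarray:
    """The baseline combination α1 - α2 + α3 (no recalibration)."""
    return channels[0] - channels[1] + channels[2]


def attention_block(nodes: np.ndarray, A: np.ndarray, params: BlockParams,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """One encoder block applied to (N, d) node states; returns (N, d)."""
    if mask is None:
        mask = np.ones(nodes.shape[0], dtype=bool)
    A = np.where(np.isneginf(A), np.finfo(float).min, A)  # tolerate -inf input
    P = attention_weights(ad.as_tensor(A), mask)
    out = attention_block_core(ad.as_tensor(nodes), P, params).data
    return out * mask[:, None]
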