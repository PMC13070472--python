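"""The full ΔΔG model: dual-pathway encoder and antisymmetric head.

Wild-type and mutant complexes are encoded by the same weights (a siamese
pair of pathways) into per-residue states u_wt, u_mut ∈ R^{Nres×d}.  The
prediction head is antisymmetric *by construction*: for each residue

    ΔΔG_i = (FFN(u_wt_i ⊕ u_mut_i) - FFN(u_mut_i ⊕ u_wt_i)) · W_ΔΔG

and the complex-level prediction is the sum over residues.  Swapping the
two pathways therefore negates the output exactly — at any weights,
trained or not — matching the physical relation between forward and
reverse mutations.  ΔΔG is reported in kcal/mol with the convention
ΔΔG = ΔG_mut - ΔG_wt (negative = affinity-enhancing).

Both pathways share one residue selection, computed symmetrically from the
wild-type/mutant pair so that a sample and its reverse select identical
subgraphs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .backside import fused_side_chain_code
from .config import ModelConfig
from .encoder import (attention_block_core, channel_squeeze_fast,
                      fuse_core, fused_attention_softmax, fused_combine,
                      gate_core, init_encoder_params, make_dropout,
                      pair_tables, _glorot, _zeros)
from .features import (EmbeddingProvider, MockEmbeddingProvider,
                       PathwayFeatures, featurize_pathway)
from .selection import ResidueSelection, select_residues
from .structure import SampleRecord

__all__ = ["HeadParams", "IGMIModel", "SampleFeatures", "stack_pathways",
           "residue_ddg", "init_head_params"]


@dataclass
class HeadParams:
    """Four-layer ReLU feed-forward head and the scalar output map."""

    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor
    W3: Tensor
    b3: Tensor
    W_ddg: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3,
                self.W_ddg]


def init_head_params(cfg: ModelConfig, rng: np.random.Generator) -> HeadParams:
    dt = np.float32 if cfg.dtype == "float32" else np.float64
    h1, h2, h3 = cfg.head_hidden
    return HeadParams(
        W1=_glorot(rng, (2 * cfg.d_model, h1), dt), b1=_zeros((h1,), dt),
        W2=_glorot(rng, (h1, h2), dt), b2=_zeros((h2,), dt),
        W3=_glorot(rng, (h2, h3), dt), b3=_zeros((h3,), dt),
        W_ddg=_glorot(rng, (h3, 1), dt),
    )


def _head_ffn(x: Tensor, p: HeadParams, keeps=None) -> Tensor:
    h = ad.relu(ad.matmul(x, p.W1) + p.b1)
    if keeps is not None:
        h = h * keeps[0]
    h = ad.relu(ad.matmul(h, p.W2) + p.b2)
    if keeps is not None:
        h = h * keeps[1]
    return ad.relu(ad.matmul(h, p.W3) + p.b3)


def residue_ddg_core(u_wt: Tensor, u_mut: Tensor, p: HeadParams,
                     dropout: float = 0.0,
                     rng: np.random.Generator | None = None) -> Tensor:
    """Per-residue antisymmetric contributions, (..., N).

    Head dropout draws one keep-mask per hidden layer and applies it to
    *both* concatenation orders, so antisymmetry stays exact even during
    training.
    """
    keeps = None
    if dropout > 0 and rng is not None:
        lead = u_wt.data.shape[:-1]
        h1, h2 = p.W1.data.shape[1], p.W2.data.shape[1]
        keeps = [
            (rng.random(lead + (h,)) >= dropout).astype(u_wt.data.dtype)
            / (1.0 - dropout)
            for h in (h1, h2)
        ]
    fwd = _head_ffn(ad.concat([u_wt, u_mut], axis=-1), p, keeps)
    rev = _head_ffn(ad.concat([u_mut, u_wt], axis=-1), p, keeps)
    return ad.matmul(fwd - rev, p.W_ddg)[..., 0]


def residue_ddg(u_wt_i: np.ndarray, u_mut_i: np.ndarray,
                head: HeadParams) -> float:
    """Antisymmetric per-residue ΔΔG contribution (kcal/mol).

    Exact antisymmetry: residue_ddg(a, b) == -residue_ddg(b, a).
    """
    out = residue_ddg_core(ad.as_tensor(np.asarray(u_wt_i, dtype=float)),
                           ad.as_tensor(np.asarray(u_mut_i, dtype=float)),
                           head)
    return float(out.data) if out.data.ndim == 0 else out.data


@dataclass
class SampleFeatures:
    """Cached model inputs for one sample (shared selection)."""

    selection: ResidueSelection
    wt: PathwayFeatures
    mut: PathwayFeatures


_STACK_FIELDS = ("node", "rbf", "contact_idx", "mask", "anchors", "frames_R",
                 "origins", "rbf_colsum", "contact_n1", "contact_n0",
                 "seqsep_hist", "pairtype_hist", "pair_comb_idx")


def stack_pathways(feats: list[PathwayFeatures]) -> dict[str, np.ndarray]:
    """Stack per-structure features into batched arrays."""
    return {k: np.stack([getattr(f, k) for f in feats])
            for k in _STACK_FIELDS}


class IGMIModel:
    """Graph-attention ΔΔG predictor over mutation-centered subgraphs."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 provider: EmbeddingProvider | None = None):
        self.config = config or ModelConfig()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.encoder = init_encoder_params(self.config, rng)
        self.head = init_head_params(self.config, rng)
        self.provider = provider or MockEmbeddingProvider(
            seed=0, embed_dim=self.config.embed_dim)
        if self.provider.embed_dim != self.config.embed_dim:
            raise ValueError("provider embed_dim does not match config")

    # -- parameters -------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return self.encoder.tensors() + self.head.tensors()

    def named_parameters(self) -> dict[str, Tensor]:
        enc = self.encoder
        out = {"node_W1": enc.node_W1, "node_b1": enc.node_b1,
               "node_W2": enc.node_W2, "node_b2": enc.node_b2,
               "out_W": enc.out_W, "out_b": enc.out_b,
               "lnf_g": enc.lnf_g, "lnf_b": enc.lnf_b}
        for i, b in enumerate(enc.blocks):
            pre = f"block{i}."
            out.update({
                pre + "rbf_w": b.channel.rbf_w,
                pre + "contact_emb": b.channel.contact_emb,
                pre + "seqsep_emb": b.channel.seqsep_emb,
                pre + "pairtype_emb": b.channel.pairtype_emb,
                pre + "pair_w": b.channel.pair_w,
                pre + "fusion_Wq": b.fusion.Wq,
                pre + "fusion_Wk": b.fusion.Wk,
                pre + "fusion_Wv": b.fusion.Wv,
                pre + "gate_W1": b.gate.W1,
                pre + "gate_W2": b.gate.W2,
                pre + "attn_Wv": b.attn_Wv,
                pre + "attn_Wo": b.attn_Wo,
                pre + "ffn_W1": b.ffn_W1,
                pre + "ffn_b1": b.ffn_b1,
                pre + "ffn_W2": b.ffn_W2,
                pre + "ffn_b2": b.ffn_b2,
                pre + "ln1_g": b.ln1_g,
                pre + "ln1_b": b.ln1_b,
                pre + "ln2_g": b.ln2_g,
                pre + "ln2_b": b.ln2_b,
            })
            if b.bsa_add_W is not None:
                out[pre + "bsa_add_W"] = b.bsa_add_W
        h = self.head
        out.update({"head_W1": h.W1, "head_b1": h.b1, "head_W2": h.W2,
                    "head_b2": h.b2, "head_W3": h.W3, "head_b3": h.b3,
                    "head_Wddg": h.W_ddg})
        return out

    # -- featurization ----------------------------------------------------
    def featurize(self, sample: SampleRecord) -> SampleFeatures:
        """Shared symmetric selection + per-pathway features."""
        sel = select_residues(sample.wt, sample.mutations,
                              n_max=self.config.n_max, companion=sample.mut)
        if sample.mut.n_residues != sample.wt.n_residues:
            raise ValueError("wild-type and mutant structures must align")
        wt = featurize_pathway(sample.wt, sel, self.provider, self.config)
        mut = featurize_pathway(sample.mut, sel, self.provider, self.config)
        return SampleFeatures(selection=sel, wt=wt, mut=mut)

    # -- forward ------------------------------------------------------------
    def encode_batch(self, batch: dict[str, np.ndarray],
                     use_proteomae: bool | None = None,
                     gate_override: tuple[float, float, float] | None = None,
                     training: bool = False,
                     rng: np.random.Generator | None = None,
                     pair_shared_dropout: bool = False
                     ) -> tuple[Tensor, Tensor, Tensor]:
        """Encode a batch of pathways.

        Returns (u, A_last, P_last): per-residue encodings (B, N, d) and the
        last block's attention logits and post-softmax weights, kept for
        interpretability.
        """
        cfg = self.config
        if use_proteomae is None:
            use_proteomae = cfg.use_proteomae
        mask = batch["mask"]
        dt = batch["node"].dtype
        mf = mask[..., None].astype(dt)
        x = ad.matmul(ad.as_tensor(batch["node"]), self.encoder.node_W1)
        x = ad.relu(x + self.encoder.node_b1)
        x = ad.matmul(x, self.encoder.node_W2) + self.encoder.node_b2
        A = P = None
        for b in self.encoder.blocks:
            T_s, T_p = pair_tables(b.channel)
            Vs, H = T_s.shape
            T_comb = (T_s.reshape((Vs, 1, H))
                      + T_p.reshape((1, 400, H))).reshape((Vs * 400, H))
            g1 = ad.matmul(ad.as_tensor(batch["rbf"]), b.channel.rbf_w)
            if gate_override is not None:
                A = fused_combine(g1, batch["contact_idx"],
                                  batch["pair_comb_idx"], T_comb,
                                  b.channel.contact_emb, None, gate_override)
            elif use_proteomae:
                z = channel_squeeze_fast(
                    batch["rbf_colsum"], batch["contact_n1"],
                    batch["contact_n0"], batch["seqsep_hist"],
                    batch["pairtype_hist"], b.channel, T_s, T_p)
                s = gate_core(fuse_core(z, b.fusion), b.gate)
                A = fused_combine(g1, batch["contact_idx"],
                                  batch["pair_comb_idx"], T_comb,
                                  b.channel.contact_emb, s)
            else:
                A = fused_combine(g1, batch["contact_idx"],
                                  batch["pair_comb_idx"], T_comb,
                                  b.channel.contact_emb, None,
                                  (1.0, 1.0, 1.0))
            P = fused_attention_softmax(A, mask)
            extra = None
            if cfg.use_bsa and cfg.bsa_mode == "add":
                code = fused_side_chain_code(P, batch["anchors"],
                                             batch["frames_R"],
                                             batch["origins"]) * cfg.bsa_scale
                extra = ad.matmul(code, b.bsa_add_W)
            drop = (make_dropout(cfg.dropout, rng, pair_shared_dropout)
                    if training else None)
            x = attention_block_core(x, P, b, extra=extra, drop=drop)
        x = ad.layer_norm(x, self.encoder.lnf_g, self.encoder.lnf_b)
        if cfg.use_bsa and cfg.bsa_mode == "concat":
            code = fused_side_chain_code(P, batch["anchors"],
                                         batch["frames_R"],
                                         batch["origins"]) * cfg.bsa_scale
            x = ad.concat([x, code], axis=-1)
        u = ad.matmul(x, self.encoder.out_W) + self.encoder.out_b
        u = u * mf
        return u, A, P

    def forward_samples(self, feats: list[SampleFeatures],
                        training: bool = False,
                        rng: np.random.Generator | None = None,
                        **encode_kw) -> Tensor:
        """Predicted ΔΔG for a list of featurized samples, shape (B,).

        Pathways are deduplicated and encoded in a content-canonical order,
        so swapping wild type and mutant (or reordering samples) reruns
        bitwise-identical GEMMs and the antisymmetry of the head is exact
        even in floating point.
        """
        pathways = [f for sf in feats for f in (sf.wt, sf.mut)]
        keys = [hashlib.sha1(f.node.tobytes() + f.anchors.tobytes()
                             + f.rbf.tobytes()).hexdigest() for f in pathways]
        unique_keys = sorted(set(keys))
        row_of = {k: i for i, k in enumerate(unique_keys)}
        unique = [pathways[keys.index(k)] for k in unique_keys]
        u, _, _ = self.encode_batch(stack_pathways(unique), training=training,
                                    rng=rng, **encode_kw)
        B = len(feats)
        wt_rows = np.array([row_of[keys[2 * i]] for i in range(B)])
        mut_rows = np.array([row_of[keys[2 * i + 1]] for i in range(B)])
        contrib = residue_ddg_core(u[wt_rows], u[mut_rows], self.head)
        m = np.stack([sf.selection.mask for sf in feats])
        return (contrib * m.astype(contrib.data.dtype)).sum(axis=-1)

    # -- public prediction API -------------------------------------------
    def predict_ddg(self, sample: SampleRecord) -> float:
        """Predicted ΔΔG (kcal/mol) for one sample."""
        return float(self.forward_samples([self.featurize(sample)]).data[0])

    def per_residue_contributions(self, sample: SampleRecord
                                  ) -> tuple[ResidueSelection, np.ndarray]:
        """Residue-level ΔΔG decomposition aligned to the selection.

        The contributions sum to :meth:`predict_ddg`; swapping wild type and
        mutant negates every entry.
        """
        sf = self.featurize(sample)
        paths = stack_pathways([sf.wt, sf.mut])
        u, _, _ = self.encode_batch(paths)
        contrib = residue_ddg_core(u[0], u[1], self.head).data
        return sf.selection, contrib * sf.selection.mask

    def attention_for_sample(self, sample: SampleRecord,
                             pathway: str = "wt") -> tuple[ResidueSelection, np.ndarray]:
        """Last-block post-softmax attention (H, N, N) for one pathway."""
        sf = self.featurize(sample)
        pf = sf.wt if pathway == "wt" else sf.mut
        _, _, P = self.encode_batch(stack_pathways([pf]))
        return sf.selection, P.data[0]

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights (``.npz``) plus a JSON manifest (``.json``)."""
        path = Path(path)
        named = self.named_parameters()
        arrays = {k: v.data for k, v in named.items()}
        np.savez(path.with_suffix(".npz"), **arrays)
        digest = hashlib.sha256(
            json.dumps(self.config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
        manifest = {
            "config": self.config.to_dict(),
            "config_hash": digest,
            "seed": self.seed,
            "shapes": {k: list(v.shape) for k, v in arrays.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path,
             provider: EmbeddingProvider | None = None) -> "IGMIModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        cfg = ModelConfig.from_dict(manifest["config"])
        model = cls(cfg, seed=manifest.get("seed", 0), provider=provider)
        with np.load(path.with_suffix(".npz")) as data:
            named = model.named_parameters()
            for k, t in named.items():
                arr = data[k]
                if arr.shape != t.data.shape:
                    raise ValueError(f"checkpoint shape mismatch for {k}")
                t.data = arr.astype(t.data.dtype)
        return model
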