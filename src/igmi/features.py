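"""SE(3)-invariant node and pair features, and the sequence-embedding provider.

All geometric features are expressed in residue-local frames or as pairwise
distances, so they are unchanged by rigid motions of the complex:

* a per-residue orthonormal frame built from the backbone (C-Cα axis,
  N-Cα Gram-Schmidt complement, right-handed cross product);
* heavy-atom coordinates mapped into that frame (up to 14 canonical slots
  with presence flags);
* Cβ-Cβ distance matrices, contact maps, signed sequence separations and
  residue-pair types over the selected subgraph.

Sequence embeddings enter through a pluggable provider.  A protein language
model adapter can be attached by implementing :class:`EmbeddingProvider`;
the built-in :class:`MockEmbeddingProvider` is a deterministic stand-in that
maps (residue type, within-chain position, seed) to unit-variance vectors,
so the full pipeline runs with no external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.spatial.distance import cdist

from .config import ModelConfig
from .constants import AA_INDEX, HEAVY_ATOMS, MAX_HEAVY_ATOMS
from .selection import ResidueSelection, selection_sequence
from .structure import ComplexStructure, ResidueRecord, get_cbeta

__all__ = [
    "LocalFrame",
    "build_local_frame",
    "local_atom_geometry",
    "pairwise_distances",
    "contact_map",
    "sequence_separation",
    "positional_encoding",
    "EmbeddingProvider",
    "MockEmbeddingProvider",
    "mock_embeddings",
    "NodeFeatures",
    "PairFeatures",
    "build_node_features",
    "build_pair_features",
    "PathwayFeatures",
    "featurize_pathway",
    "rbf_expand",
    "PAD_DISTANCE",
]

PAD_DISTANCE = 1.0e4  # sentinel distance for padding slots, Å


@dataclass
class LocalFrame:
    """Right-handed orthonormal residue frame; columns of R are the axes."""

    R: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.abs(self.R.T @ self.R - np.eye(3)).max() > 1e-6:
            raise ValueError("frame rotation is not orthonormal")
        if abs(np.linalg.det(self.R) - 1.0) > 1e-6:
            raise ValueError("frame rotation is not proper (det != +1)")


def build_local_frame(residue: ResidueRecord) -> LocalFrame:
    """Backbone frame: e1 along C-Cα, e2 the N-Cα complement, e3 = e1 x e2."""
    if not residue.complete:
        raise ValueError(f"residue {residue.key} is incomplete")
    ca = residue.coords("CA")
    v1 = residue.coords("C") - ca
    n1 = np.linalg.norm(v1)
    if n1 < 1e-3:
        raise ValueError(f"residue {residue.key}: degenerate frame (C on CA)")
    e1 = v1 / n1
    v2 = residue.coords("N") - ca
    v2 = v2 - (v2 @ e1) * e1
    n2 = np.linalg.norm(v2)
    if n2 < 1e-3:
        raise ValueError(f"residue {residue.key}: degenerate frame "
                         "(collinear N, CA, C)")
    e2 = v2 / n2
    e3 = np.cross(e1, e2)
    return LocalFrame(R=np.stack([e1, e2, e3], axis=1), origin=ca)


def local_atom_geometry(residue: ResidueRecord, frame: LocalFrame) -> np.ndarray:
    """Heavy atoms in the residue frame, padded to 14 slots.

    Returns a 56-vector: 14x3 local coordinates (canonical atom-name order
    for the residue type, absent atoms zero) followed by 14 presence flags.
    The CA slot is (0, 0, 0) by construction.
    """
    coords = np.zeros((MAX_HEAVY_ATOMS, 3))
    flags = np.zeros(MAX_HEAVY_ATOMS)
    for slot, name in enumerate(HEAVY_ATOMS[residue.aa]):
        atom = residue.atom(name)
        if atom is None:
            continue
        coords[slot] = frame.R.T @ (atom.coords - frame.origin)
        flags[slot] = 1.0
    return np.concatenate([coords.ravel(), flags])


def _selected_cbeta(structure: ComplexStructure,
                    selection: ResidueSelection) -> np.ndarray:
    out = np.zeros((selection.n_max, 3))
    for slot, idx in enumerate(selection.indices):
        if selection.mask[slot]:
            out[slot] = get_cbeta(structure.residues[idx])
    return out


def pairwise_distances(structure: ComplexStructure,
                       selection: ResidueSelection) -> np.ndarray:
    """Cβ-Cβ Euclidean distance matrix over the selection (Å).

    Padding rows/columns carry the sentinel ``PAD_DISTANCE``.
    """
    cb = _selected_cbeta(structure, selection)
    d = cdist(cb, cb)
    invalid = ~selection.mask
    d[invalid, :] = PAD_DISTANCE
    d[:, invalid] = PAD_DISTANCE
    return d


def contact_map(D: np.ndarray, threshold: float = 8.0) -> np.ndarray:
    """Binary contact map: D[i, j] <= threshold (closed), zero diagonal.

    The sentinel padding distance never passes the threshold, so padding
    rows/columns are zero.
    """
    if threshold <= 0:
        raise ValueError("contact threshold must be positive")
    c = (D <= threshold).astype(np.int8)
    np.fill_diagonal(c, 0)
    return c


def sequence_separation(structure: ComplexStructure,
                        selection: ResidueSelection,
                        clip: int = 32) -> np.ndarray:
    """Signed sequence separation resseq_j - resseq_i, clipped to ±clip.

    Cross-chain pairs carry the sentinel ``clip + 1``; padding entries are
    zero.  Within a chain the matrix is antisymmetric.
    """
    n = selection.n_max
    out = np.zeros((n, n), dtype=int)
    chains = np.array([structure.residues[i].chain_id if m else ""
                       for i, m in zip(selection.indices, selection.mask)])
    seq = np.array([structure.residues[i].resseq if m else 0
                    for i, m in zip(selection.indices, selection.mask)])
    valid = selection.mask
    same = (chains[:, None] == chains[None, :]) & valid[:, None] & valid[None, :]
    diff = np.clip(seq[None, :] - seq[:, None], -clip, clip)
    out[same] = diff[same]
    cross = (~same) & valid[:, None] & valid[None, :]
    out[cross] = clip + 1
    return out


def seqsep_to_index(seqsep: np.ndarray, clip: int = 32) -> np.ndarray:
    """Map signed separations to a compact embedding vocabulary.

    Within-chain values shift to [0, 2*clip]; the cross-chain sentinel maps
    to 2*clip + 1.
    """
    idx = np.where(seqsep == clip + 1, 2 * clip + 1, seqsep + clip)
    return idx.astype(int)


def positional_encoding(positions: np.ndarray, dim: int = 16) -> np.ndarray:
    """Sinusoidal encoding of within-chain residue indices."""
    positions = np.asarray(positions, dtype=float)
    half = dim // 2
    freqs = 1.0 / (10000.0 ** (np.arange(half) / max(half, 1)))
    ang = positions[..., None] * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=-1)


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Plug-in interface for per-residue sequence embeddings.

    ``embed`` receives one amino-acid string per chain and returns one
    (length, embed_dim) matrix per chain; it must be deterministic for a
    fixed input.
    """

    embed_dim: int

    def embed(self, chains: list[str]) -> list[np.ndarray]: ...


class MockEmbeddingProvider:
    """Deterministic stand-in for a protein-language-model embedder.

    Each row depends only on (residue type, position in the given string,
    seed); entries are draws from a unit-variance normal.
    """

    def __init__(self, seed: int = 0, embed_dim: int = 32):
        self.seed = int(seed)
        self.embed_dim = int(embed_dim)
        self._cache: dict[tuple[str, int], np.ndarray] = {}

    def _row(self, aa: str, pos: int) -> np.ndarray:
        key = (aa, pos)
        row = self._cache.get(key)
        if row is None:
            rng = np.random.default_rng([self.seed, AA_INDEX[aa], pos])
            row = rng.standard_normal(self.embed_dim)
            self._cache[key] = row
        return row

    def embed(self, chains: list[str]) -> list[np.ndarray]:
        out = []
        for seq in chains:
            if seq:
                out.append(np.stack([self._row(aa, i) for i, aa in enumerate(seq)]))
            else:
                out.append(np.zeros((0, self.embed_dim)))
        return out


def mock_embeddings(chains: list[str], seed: int = 0,
                    embed_dim: int = 32) -> list[np.ndarray]:
    """Functional form of :class:`MockEmbeddingProvider`."""
    return MockEmbeddingProvider(seed=seed, embed_dim=embed_dim).embed(chains)


@dataclass
class NodeFeatures:
    """Per-residue features over the selection (padding rows zero)."""

    aa_onehot: np.ndarray   # (n_max, 20)
    pos_enc: np.ndarray     # (n_max, P)
    local_geom: np.ndarray  # (n_max, 56)
    seq_embed: np.ndarray   # (n_max, E)
    mask: np.ndarray        # (n_max,)

    @property
    def concat(self) -> np.ndarray:
        return np.concatenate(
            [self.aa_onehot, self.pos_enc, self.local_geom, self.seq_embed],
            axis=-1)


@dataclass
class PairFeatures:
    """Pairwise descriptors over the selection."""

    D: np.ndarray          # (n_max, n_max) distances, Å
    contact: np.ndarray    # binary contact map
    seqsep: np.ndarray     # signed sequence separation (sentinel cross-chain)
    pairtype: np.ndarray   # 20x20 residue-pair-type index
    mask: np.ndarray       # (n_max,) valid slots


def build_node_features(structure: ComplexStructure,
                        selection: ResidueSelection,
                        provider: EmbeddingProvider,
                        config: ModelConfig = ModelConfig()) -> NodeFeatures:
    n = selection.n_max
    aa_onehot = np.zeros((n, 20))
    pos_enc = np.zeros((n, config.pos_enc_dim))
    local_geom = np.zeros((n, 56))
    seq_embed = np.zeros((n, provider.embed_dim))

    # within-chain rank of every residue of the structure
    rank: dict[int, int] = {}
    counts: dict[str, int] = {}
    for i, res in enumerate(structure.residues):
        rank[i] = counts.get(res.chain_id, 0)
        counts[res.chain_id] = rank[i] + 1

    chains = structure.chain_ids
    seqs = selection_sequence(structure, selection)
    embeds = provider.embed([seqs[c] for c in chains])
    embed_by_chain = dict(zip(chains, embeds))
    chain_cursor: dict[str, int] = {c: 0 for c in chains}

    for slot, idx in enumerate(selection.indices):
        if not selection.mask[slot]:
            continue
        res = structure.residues[idx]
        aa_onehot[slot, AA_INDEX[res.aa]] = 1.0
        pos_enc[slot] = positional_encoding(np.array(rank[idx]),
                                            config.pos_enc_dim)
        frame = build_local_frame(res)
        local_geom[slot] = local_atom_geometry(res, frame)
        cur = chain_cursor[res.chain_id]
        seq_embed[slot] = embed_by_chain[res.chain_id][cur]
        chain_cursor[res.chain_id] = cur + 1
    return NodeFeatures(aa_onehot, pos_enc, local_geom, seq_embed,
                        selection.mask.copy())


def build_pair_features(structure: ComplexStructure,
                        selection: ResidueSelection,
                        config: ModelConfig = ModelConfig()) -> PairFeatures:
    D = pairwise_distances(structure, selection)
    contact = contact_map(D, config.contact_threshold)
    seqsep = sequence_separation(structure, selection, config.seqsep_clip)
    aa_idx = np.array([AA_INDEX[structure.residues[i].aa] if m else 0
                       for i, m in zip(selection.indices, selection.mask)])
    pairtype = aa_idx[:, None] * 20 + aa_idx[None, :]
    return PairFeatures(D, contact, seqsep, pairtype, selection.mask.copy())


def rbf_expand(D: np.ndarray, bins: int = 16, r_max: float = 20.0) -> np.ndarray:
    """Gaussian radial-basis expansion of distances, centers on [0, r_max]."""
    centers = np.linspace(0.0, r_max, bins)
    width = centers[1] - centers[0]
    return np.exp(-((D[..., None] - centers) ** 2) / (2.0 * width ** 2))


@dataclass
class PathwayFeatures:
    """Everything the encoder needs for one structure, as plain arrays.

    Besides the raw pair descriptors, a few constant aggregates are
    precomputed once per structure so the encoder's channel-squeeze step can
    run on small per-residue arrays instead of materializing masked
    (N, N, H) channel tensors: the column sums of the radial-basis
    expansion, per-column valid/contact counts, and per-column histograms of
    the sequence-separation and pair-type vocabularies (valid pairs only).
    """

    node: np.ndarray         # (n_max, F) concatenated node features
    rbf: np.ndarray          # (n_max, n_max, K)
    contact_idx: np.ndarray  # (n_max, n_max) in {0, 1}
    seqsep_idx: np.ndarray   # (n_max, n_max) vocabulary indices
    pairtype_idx: np.ndarray # (n_max, n_max) in [0, 400)
    mask: np.ndarray         # (n_max,) bool
    anchors: np.ndarray      # (n_max, 3) Cβ coordinates (zeros on padding)
    frames_R: np.ndarray     # (n_max, 3, 3) local frames (identity on padding)
    origins: np.ndarray      # (n_max, 3) Cα coordinates
    # constant aggregates for the channel squeeze (see class docstring)
    rbf_colsum: np.ndarray   # (n_max, K) Σ_i rbf[i, j, :]
    contact_n1: np.ndarray   # (n_max,) valid contacts per column
    contact_n0: np.ndarray   # (n_max,) valid non-contacts per column
    seqsep_hist: np.ndarray  # (n_max, V_seqsep)
    pairtype_hist: np.ndarray# (n_max, 400)
    pair_comb_idx: np.ndarray# (n_max, n_max) seqsep_idx * 400 + pairtype_idx


def featurize_pathway(structure: ComplexStructure,
                      selection: ResidueSelection,
                      provider: EmbeddingProvider,
                      config: ModelConfig = ModelConfig()) -> PathwayFeatures:
    node = build_node_features(structure, selection, provider, config)
    pair = build_pair_features(structure, selection, config)
    n = selection.n_max
    anchors = _selected_cbeta(structure, selection)
    frames_R = np.tile(np.eye(3), (n, 1, 1))
    origins = np.zeros((n, 3))
    for slot, idx in enumerate(selection.indices):
        if selection.mask[slot]:
            fr = build_local_frame(structure.residues[idx])
            frames_R[slot] = fr.R
            origins[slot] = fr.origin
    dt = np.float32 if config.dtype == "float32" else np.float64
    # block normalization: scale each node-feature block so its expected
    # squared norm is O(1) — otherwise the wide unit-variance embedding
    # block (E dims) and the Å-scale geometry block drown the 20-dim
    # residue-type one-hot in the model input
    node_mat = np.concatenate([
        node.aa_onehot,
        node.pos_enc / np.sqrt(config.pos_enc_dim / 2.0),
        node.local_geom / np.sqrt(MAX_HEAVY_ATOMS),
        node.seq_embed / np.sqrt(provider.embed_dim),
    ], axis=-1)
    rbf = rbf_expand(pair.D, config.rbf_bins, config.rbf_max).astype(dt)
    contact_idx = pair.contact.astype(int)
    seqsep_idx = seqsep_to_index(pair.seqsep, config.seqsep_clip)
    pairtype_idx = pair.pairtype.astype(int)
    pm = selection.mask[:, None] & selection.mask[None, :]
    jj = np.broadcast_to(np.arange(n)[None, :], (n, n))
    vi, vj = np.nonzero(pm)
    seqsep_hist = np.zeros((n, config.seqsep_vocab), dtype=dt)
    np.add.at(seqsep_hist, (vj, seqsep_idx[vi, vj]), 1.0)
    pairtype_hist = np.zeros((n, 400), dtype=dt)
    np.add.at(pairtype_hist, (vj, pairtype_idx[vi, vj]), 1.0)
    contact_n1 = (contact_idx * pm).sum(axis=0).astype(dt)
    contact_n0 = pm.sum(axis=0).astype(dt) - contact_n1
    return PathwayFeatures(
        node=node_mat.astype(dt),
        rbf=rbf,
        contact_idx=contact_idx,
        seqsep_idx=seqsep_idx,
        pairtype_idx=pairtype_idx,
        mask=selection.mask.copy(),
        anchors=anchors.astype(dt),
        frames_R=frames_R.astype(dt),
        origins=origins.astype(dt),
        rbf_colsum=(rbf * pm[..., None]).sum(axis=0).astype(dt),
        contact_n1=contact_n1,
        contact_n0=contact_n0,
        seqsep_hist=seqsep_hist,
        pairtype_hist=pairtype_hist,
        pair_comb_idx=(seqsep_idx * 400 + pairtype_idx).astype(np.int64),
    )
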