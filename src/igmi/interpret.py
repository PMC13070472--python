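"""Attention interpretability: residue regions and high-attention residues.

Residues are partitioned into four mutually exclusive regions relative to a
mutated complex:

* ``class_cross``      — near a mutation site *and* at the interface;
* ``mut_around``       — within the cutoff of a mutation site only;
* ``interface_around`` — at the interface only;
* ``background``       — neither.

"Near" is any heavy-atom pair within the cutoff (5 Å by default); the
interface test is a distance proxy — any heavy atom within the cutoff of
the opposite partner — rather than a buried-surface-area definition, and is
labeled as such in outputs.  Mutation-site residues themselves count as
near the mutation.

High-attention residues are ranked per head by *received* attention: the
column sum of the post-softmax attention over valid queries.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._autodiff import as_tensor, masked_softmax
from .structure import ComplexStructure, MutationSpec

__all__ = ["RegionLabel", "classify_regions", "top_attention_residues",
           "attention_scores", "region_summary"]


class RegionLabel(str, Enum):
    CLASS_CROSS = "class_cross"
    MUT_AROUND = "mut_around"
    INTERFACE_AROUND = "interface_around"
    BACKGROUND = "background"


def _residue_atoms(structure: ComplexStructure) -> list[np.ndarray]:
    return [np.array([a.coords for a in r.atoms]) for r in structure.residues]


def classify_regions(structure: ComplexStructure,
                     mutations: list[MutationSpec],
                     cutoff: float = 5.0) -> list[RegionLabel]:
    """Four-region partition of all residues (heavy-atom distances, Å)."""
    if not mutations:
        raise ValueError("at least one mutation is required")
    atoms = _residue_atoms(structure)
    sites = []
    for spec in mutations:
        idx = structure.find(spec.chain_id, spec.resseq)
        if idx is None:
            raise ValueError(f"mutation site {spec.code} not in structure")
        sites.append(idx)
    site_tree = cKDTree(np.vstack([atoms[i] for i in sites]))
    partners = structure.partner_labels()
    side_coords = [np.vstack([a for a, p in zip(atoms, partners) if p == s])
                   for s in (0, 1)]
    side_trees = [cKDTree(c) for c in side_coords]
    labels = []
    for i, res_atoms in enumerate(atoms):
        near = (i in sites or
                bool((site_tree.query(res_atoms, k=1)[0] <= cutoff).any()))
        other = side_trees[1 - partners[i]]
        interface = bool((other.query(res_atoms, k=1)[0] <= cutoff).any())
        if near and interface:
            labels.append(RegionLabel.CLASS_CROSS)
        elif near:
            labels.append(RegionLabel.MUT_AROUND)
        elif interface:
            labels.append(RegionLabel.INTERFACE_AROUND)
        else:
            labels.append(RegionLabel.BACKGROUND)
    return labels


def attention_scores(A: np.ndarray,
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Received attention per residue and head: column sums of softmax(A).

    ``A`` may be attention logits (H, N, N) or already row-stochastic; in
    the latter case pass it through unchanged by giving row sums of one.
    """
    A = np.asarray(A, dtype=float)
    if mask is None:
        mask = np.ones(A.shape[-1], dtype=bool)
    sub = A[:, mask][:, :, mask]
    row_stochastic = (np.isfinite(sub).all() and (sub >= 0).all()
                      and np.allclose(sub.sum(-1), 1.0, atol=1e-6))
    if row_stochastic:
        P = np.where(mask[None, :, None] & mask[None, None, :], A, 0.0)
    else:
        Af = np.where(np.isneginf(A), np.finfo(float).min, A)
        P = masked_softmax(as_tensor(Af), mask[None, None, :], axis=-1).data
        P = np.where(mask[None, :, None], P, 0.0)
    return P.sum(axis=1)  # (H, N): attention received by each key residue


def top_attention_residues(A: np.ndarray, k: int = 5,
                           mask: np.ndarray | None = None
                           ) -> list[list[int]]:
    """Per-head top-k residues by received attention (ties: lower index)."""
    scores = attention_scores(A, mask)
    if mask is None:
        mask = np.ones(A.shape[-1], dtype=bool)
    valid = np.nonzero(mask)[0]
    out = []
    for h in range(scores.shape[0]):
        order = sorted(valid, key=lambda i: (-scores[h, i], i))
        out.append([int(i) for i in order[:k]])
    return out


def region_summary(labels: list[RegionLabel],
                   top_lists: list[list[int]],
                   scores: np.ndarray) -> pd.DataFrame:
    """Region-wise statistics of the high-attention residues.

    ``labels`` aligns with the residue axis of ``scores`` (H, N);
    ``top_lists`` holds per-head top-k index lists.  Fractions sum to 1.
    """
    rows = []
    flat = [(h, i) for h, lst in enumerate(top_lists) for i in lst]
    total = len(flat)
    for region in RegionLabel:
        hits = [(h, i) for h, i in flat if labels[i] == region]
        vals = np.array([scores[h, i] for h, i in hits], dtype=float)
        rows.append({
            "region": region.value,
            "count": len(hits),
            "fraction": len(hits) / total if total else 0.0,
            "mean_score": float(vals.mean()) if len(vals) else np.nan,
            "q25": float(np.percentile(vals, 25)) if len(vals) else np.nan,
            "median": float(np.median(vals)) if len(vals) else np.nan,
            "q75": float(np.percentile(vals, 75)) if len(vals) else np.nan,
        })
    return pd.DataFrame(rows)
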