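"""Mutation-centered residue selection.

The model never sees a whole complex: it operates on a fixed-size subgraph
of ``n_max`` residues (128 by default) centered on the mutation sites, so
attention cost is O(n_max²) regardless of complex size.  Residues are ranked
by their minimum Cβ-Cβ distance to any mutation site (sites themselves rank
first) and the ``n_max`` nearest are kept, re-sorted to global residue
order.  Ties break on (chain, resseq, icode), making the rule deterministic
and — because it is purely distance-based — invariant under rigid motion of
the complex.

When a companion structure is given (the other pathway of a wild-type /
mutant pair), the ranking key is the minimum over *both* structures, so a
sample and its reverse (wt and mut swapped) select exactly the same
residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import ComplexStructure, MutationSpec, get_cbeta

__all__ = ["ResidueSelection", "select_residues", "selection_sequence"]


@dataclass
class ResidueSelection:
    """Indices into ``ComplexStructure.residues`` plus padding mask.

    ``indices`` has length ``n_max``; padding slots hold -1 and are False in
    ``mask``.  Valid indices are strictly increasing in global residue
    order.
    """

    indices: np.ndarray
    mask: np.ndarray
    n_max: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.indices.shape != (self.n_max,) or self.mask.shape != (self.n_max,):
            raise ValueError("indices and mask must have length n_max")
        valid = self.indices[self.mask]
        if len(valid) and np.any(np.diff(valid) <= 0):
            raise ValueError("valid indices must be strictly increasing")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def valid_indices(self) -> np.ndarray:
        return self.indices[self.mask]


def _site_indices(structure: ComplexStructure,
                  mutations: list[MutationSpec]) -> list[int]:
    sites = []
    for spec in mutations:
        idx = structure.find(spec.chain_id, spec.resseq)
        if idx is None:
            raise ValueError(f"mutation site {spec.code} not found in structure")
        sites.append(idx)
    return sites


def _min_site_distance(structure: ComplexStructure, sites: list[int],
                       candidates: list[int]) -> np.ndarray:
    cb = np.array([get_cbeta(structure.residues[i]) for i in candidates])
    site_cb = np.array([get_cbeta(structure.residues[i]) for i in sites])
    d = np.linalg.norm(cb[:, None, :] - site_cb[None, :, :], axis=-1)
    return d.min(axis=1)


def select_residues(structure: ComplexStructure,
                    mutations: list[MutationSpec],
                    n_max: int = 128,
                    companion: ComplexStructure | None = None) -> ResidueSelection:
    """Select the ``n_max`` residues nearest to the mutation sites.

    Only complete residues (backbone N/CA/C present) are candidates.  With
    ``companion`` set, the distance key is the minimum over both structures
    (see module docstring).
    """
    if not mutations:
        raise ValueError("at least one mutation is required")
    sites = _site_indices(structure, mutations)
    for i in sites:
        if not structure.residues[i].complete:
            raise ValueError(f"mutation-site residue {structure.residues[i].key} "
                             "is incomplete (missing backbone atoms)")
    if n_max < len(set(sites)):
        raise ValueError(f"n_max={n_max} is smaller than the number of "
                         f"mutation sites ({len(set(sites))})")
    candidates = [i for i, r in enumerate(structure.residues) if r.complete]
    key = _min_site_distance(structure, sites, candidates)
    if companion is not None:
        if companion.n_residues != structure.n_residues:
            raise ValueError("companion structure must align residue-for-residue")
        key = np.minimum(key, _min_site_distance(
            companion, _site_indices(companion, mutations), candidates))
    site_set = set(sites)
    key = np.where(np.isin(candidates, list(site_set)), 0.0, key)
    order = sorted(range(len(candidates)),
                   key=lambda k: (key[k], structure.residues[candidates[k]].key))
    chosen = sorted(candidates[k] for k in order[:n_max])
    indices = np.full(n_max, -1, dtype=int)
    mask = np.zeros(n_max, dtype=bool)
    indices[:len(chosen)] = chosen
    mask[:len(chosen)] = True
    return ResidueSelection(indices=indices, mask=mask, n_max=n_max)


def selection_sequence(structure: ComplexStructure,
                       selection: ResidueSelection) -> dict[str, str]:
    """Per-chain amino-acid strings restricted to the selected residues.

    Every chain of the structure gets an entry (possibly empty); order
    within each string follows residue order.
    """
    out = {c: [] for c in structure.chain_ids}
    for idx in selection.valid_indices:
        res = structure.residues[idx]
        out[res.chain_id].append(res.aa)
    return {c: "".join(v) for c, v in out.items()}
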