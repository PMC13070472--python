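"""Cross-validation fold construction with independence certificates.

Three protocols are supported:

* **RSCV** — random split: samples shuffled into k folds of near-equal size.
* **SSCV** — split by structure: complexes sharing any structural-domain
  annotation (e.g. ECOD identifiers, treated as opaque strings) are merged
  into groups, and whole groups are assigned to folds, so no domain occurs
  in two folds.
* **C3** — split by protein partner: samples sharing any partner protein
  land in the same fold, so no partner crosses the train/test boundary.

Grouping uses connected components (the minimal closure of the sharing
relation); balancing uses the classic longest-processing-time greedy rule —
largest group first into the currently smallest fold — which is
deterministic for canonicalized (sorted) input.  Every assignment can be
checked by :func:`verify_independence`, which re-derives the constraint
exhaustively and reports violations (an empty list certifies the split).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["FoldAssignment", "rscv_folds", "sscv_folds", "c3_folds",
           "verify_independence", "train_val_test_split"]


@dataclass
class FoldAssignment:
    """Sample → fold map with the verifier's certificate."""

    fold_of: dict[str, int]
    k: int
    mode: str  # "RSCV" | "SSCV" | "C3"
    certificate: dict = field(default_factory=dict)

    def folds(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.k)]
        for sid in sorted(self.fold_of):
            out[self.fold_of[sid]].append(sid)
        return out

    @property
    def fold_sizes(self) -> list[int]:
        return [len(f) for f in self.folds()]


def rscv_folds(sample_ids, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Random k-fold split; fold sizes differ by at most one."""
    ids = sorted(str(s) for s in sample_ids)
    if len(ids) < k:
        raise ValueError(f"cannot make {k} folds from {len(ids)} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold_of = {ids[p]: i % k for i, p in enumerate(perm)}
    fa = FoldAssignment(fold_of, k, "RSCV")
    fa.certificate = verify_independence(fa, {})
    return fa


def _grouped_folds(sample_to_entities: dict[str, set[str]], k: int,
                   mode: str) -> FoldAssignment:
    """Greedy balanced assignment of sharing-closed sample groups."""
    g = nx.Graph()
    for sid in sample_to_entities:
        g.add_node(("s", sid))
        for ent in sample_to_entities[sid]:
            g.add_edge(("s", sid), ("e", ent))
    groups: list[list[str]] = []
    for comp in nx.connected_components(g):
        samples = sorted(n[1] for n in comp if n[0] == "s")
        if samples:
            groups.append(samples)
    if k > len(groups):
        raise ValueError(f"cannot form {k} non-empty folds from "
                         f"{len(groups)} independent groups")
    # LPT: largest group first, into the currently smallest fold
    groups.sort(key=lambda grp: (-len(grp), grp[0]))
    sizes = [0] * k
    fold_of: dict[str, int] = {}
    for grp in groups:
        target = int(np.argmin(sizes))
        for sid in grp:
            fold_of[sid] = target
        sizes[target] += len(grp)
    fa = FoldAssignment(fold_of, k, mode)
    fa.certificate = verify_independence(fa, sample_to_entities)
    return fa


def sscv_folds(sample_to_complex: dict[str, str],
               complex_to_domains: dict[str, set[str]],
               k: int = 10) -> FoldAssignment:
    """Structure-split folds: no structural domain occurs in two folds.

    Complexes with an empty domain set are independent groups of their own.
    """
    sample_to_entities: dict[str, set[str]] = {}
    for sid, cid in sample_to_complex.items():
        doms = set(complex_to_domains.get(cid, set()))
        # tie samples of one complex together even without domain annotations
        sample_to_entities[str(sid)] = {f"complex:{cid}"} | {
            f"domain:{d}" for d in doms}
    return _grouped_folds(sample_to_entities, k, "SSCV")


def c3_folds(sample_to_partners: dict[str, set[str]],
             k: int = 10) -> FoldAssignment:
    """Partner-independent folds: no protein partner occurs in two folds."""
    ents = {str(s): {f"partner:{p}" for p in ps}
            for s, ps in sample_to_partners.items()}
    return _grouped_folds(ents, k, "C3")


def verify_independence(assignment: FoldAssignment,
                        sample_to_entities: dict[str, set[str]]) -> dict:
    """Exhaustively re-check the fold constraint.

    ``sample_to_entities`` maps each sample to the entities (domains or
    partners) that must not cross folds; pass an empty mapping for RSCV.
    Returns a certificate with the (hopefully empty) violation list and the
    fold-size table.
    """
    entity_folds: dict[str, set[int]] = {}
    for sid, fold in assignment.fold_of.items():
        for ent in sample_to_entities.get(sid, ()):  # noqa: B909
            entity_folds.setdefault(ent, set()).add(fold)
    violations = [{"entity": ent, "folds": sorted(folds)}
                  for ent, folds in sorted(entity_folds.items())
                  if len(folds) > 1]
    return {
        "mode": assignment.mode,
        "n_samples": len(assignment.fold_of),
        "fold_sizes": assignment.fold_sizes,
        "violations": violations,
    }


def train_val_test_split(assignment: FoldAssignment, test_fold: int,
                         val_fraction: float = 1.0 / 9.0,
                         seed: int = 0) -> tuple[list[str], list[str], list[str]]:
    """8:1:1-style split derived from a fold assignment.

    The given fold is the test set (≈1/k of the data); the remaining
    samples are split into validation (``val_fraction`` of them, 1/9 by
    default so the overall ratio is ≈8:1:1 at k=10) and training.
    """
    if not 0 <= test_fold < assignment.k:
        raise ValueError("test_fold out of range")
    test = assignment.folds()[test_fold]
    rest = sorted(s for s, f in assignment.fold_of.items() if f != test_fold)
    rng = np.random.default_rng(seed)
    n_val = int(round(val_fraction * len(rest)))
    perm = rng.permutation(len(rest))
    val = sorted(rest[i] for i in perm[:n_val])
    trainset = sorted(rest[i] for i in perm[n_val:])
    return trainset, val, test
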