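"""Residue-atom coupled attention (BackSideAttention).

Residue-level attention is projected onto side-chain anchor coordinates
(Cβ, virtual for glycine): the post-softmax attention of each head maps the
anchor cloud to one expected side-chain position per residue and head.
Expressing that point in the residue's backbone frame yields three
SE(3)-invariant descriptors per head — position ξ ∈ R³, distance ζ = ‖ξ‖
and unit direction ψ = ξ/ζ (ψ = 0 when ζ vanishes) — which concatenate to
the per-residue side-chain geometric code of width 7H.

Because the attention rows are stochastic over valid keys only, the
projected points transform rigidly with the complex and the descriptors are
exactly invariant under rigid motions.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = ["project_points", "local_descriptors", "assemble_bsa",
           "side_chain_code_core", "fused_side_chain_code"]

_EPS = 1e-8  # ζ below this is treated as zero (degenerate direction rule)


def project_points(A: np.ndarray, f: np.ndarray,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Attention-weighted anchor positions, softmax(A) @ f.

    ``A`` is (H, N, N) attention logits (row softmax over the key axis,
    restricted to ``mask``); ``f`` is (N, 3) anchor coordinates.  Returns
    (H, N, 3).
    """
    A = np.asarray(A, dtype=float)
    if mask is None:
        mask = np.ones(A.shape[-1], dtype=bool)
    A = np.where(np.isneginf(A), np.finfo(float).min, A)
    P = ad.masked_softmax(ad.as_tensor(A), mask[None, None, :], axis=-1)
    return ad.matmul(P, ad.as_tensor(np.asarray(f, dtype=float))).data


def local_descriptors(f_mdim: np.ndarray, frames_R: np.ndarray,
                      origins: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame-local (ξ, ζ, ψ) descriptors of projected points.

    ``f_mdim`` is (H, N, 3); ``frames_R`` is (N, 3, 3) and ``origins``
    (N, 3) per-residue frames.  ζ = ‖ξ‖ exactly; ψ = 0 when ζ < 1e-8.
    """
    f_mdim = np.asarray(f_mdim, dtype=float)
    g = np.einsum("nij,hni->hnj", np.asarray(frames_R, dtype=float),
                  f_mdim - np.asarray(origins, dtype=float)[None, :, :])
    zeta = np.linalg.norm(g, axis=-1)
    safe = np.where(zeta < _EPS, 1.0, zeta)
    psi = np.where((zeta < _EPS)[..., None], 0.0, g / safe[..., None])
    return g, zeta, psi


def assemble_bsa(xi: np.ndarray, zeta: np.ndarray,
                 psi: np.ndarray) -> np.ndarray:
    """Concatenate (ξ ⊕ ζ ⊕ ψ) across heads → (N, 7H) side-chain code."""
    H, N = zeta.shape
    per_head = np.concatenate([xi, zeta[..., None], psi], axis=-1)  # (H, N, 7)
    return np.moveaxis(per_head, 0, 1).reshape(N, 7 * H)


def side_chain_code_core(P: Tensor, anchors: np.ndarray,
                         frames_R: np.ndarray, origins: np.ndarray) -> Tensor:
    """Differentiable batched side-chain code used inside the encoder.

    ``P`` is the post-softmax attention (..., H, N, N); anchors/frames are
    constant arrays of shape (..., N, 3) and (..., N, 3, 3).  Returns the
    (..., N, 7H) code.  The direction uses a smooth 1/(ζ + 1e-8)
    normalisation so it stays differentiable at the origin.
    """
    anchors = np.expand_dims(np.asarray(anchors), -3)   # (..., 1, N, 3)
    fm = ad.matmul(P, ad.as_tensor(anchors))            # (..., H, N, 3)
    org = np.expand_dims(origins, -3)                   # (..., 1, N, 3)
    rel = fm - ad.as_tensor(org)
    R = ad.as_tensor(np.expand_dims(frames_R, -4))      # (..., 1, N, 3, 3)
    g = ad.matmul(rel.reshape(rel.shape[:-1] + (1, 3)), R)
    g = g.reshape(g.shape[:-2] + (3,))                  # (..., H, N, 3) local
    zeta = ad.sqrt((g * g).sum(axis=-1, keepdims=True) + 1e-24)
    psi = g / (zeta + _EPS)
    code = ad.concat([g, zeta, psi], axis=-1)           # (..., H, N, 7)
    code = code.moveaxis(-3, -2)                        # (..., N, H, 7)
    H = code.shape[-2]
    return code.reshape(code.shape[:-2] + (7 * H,))


def fused_side_chain_code(P: Tensor, anchors: np.ndarray,
                          frames_R: np.ndarray,
                          origins: np.ndarray) -> Tensor:
    """Numba-fused batched equivalent of :func:`side_chain_code_core`.

    ``P`` must be (B, H, N, N); anchors/frames/origins are constant batched
    arrays.  Gradients flow into ``P`` only.
    """
    from . import _kernels
    code, gsave = _kernels.bsa_fwd(
        P.data, np.ascontiguousarray(anchors),
        np.ascontiguousarray(frames_R), np.ascontiguousarray(origins), _EPS)

    def backward(g: np.ndarray):
        return (_kernels.bsa_bwd(np.ascontiguousarray(g), gsave, P.data,
                                 np.ascontiguousarray(anchors),
                                 np.ascontiguousarray(frames_R), _EPS),)

    return ad._op(code, (P,), backward)
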