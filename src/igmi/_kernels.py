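"""Fused Numba kernels for the encoder's hot loops.

Two pipelines dominate the training cost at desk scale and are fused here
into single passes with hand-written vector-Jacobian products:

* channel combine — assembling the attention logits
  ``A[b,h,i,j] = c1 g1 - c2 g2 + c3 g3`` from the radial-basis gemm output,
  the contact embedding and the pair-vocabulary table, written directly in
  head-first layout;
* masked key softmax over (B, H, N, N) logits.

The kernels are loop-level re-statements of the reference operations in
:mod:`igmi.encoder`; tests assert their equivalence.  All loops are
sequential and per-element independent, so results do not depend on batch
composition.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["combine_fwd", "combine_bwd", "softmax_fwd", "softmax_bwd",
           "bsa_fwd", "bsa_bwd"]


@njit(cache=True, fastmath=True)
def combine_fwd(g1, contact, comb_idx, tcomb, e0, e1, c1, c2, c3):
    """A[b,h,i,j] = c1[b]*g1[b,i,j,h] - c2[b]*g2 + c3[b]*tcomb[idx,h].

    g2 is the contact-channel logit contact*(e1-e0)+e0.
    """
    B, N, _, H = g1.shape
    A = np.empty((B, H, N, N), dtype=g1.dtype)
    for b in range(B):
        for i in range(N):
            for j in range(N):
                ci = contact[b, i, j]
                t = comb_idx[b, i, j]
                for h in range(H):
                    g2 = ci * (e1[h] - e0[h]) + e0[h]
                    A[b, h, i, j] = (c1[b] * g1[b, i, j, h]
                                     - c2[b] * g2 + c3[b] * tcomb[t, h])
    return A


@njit(cache=True, fastmath=True)
def combine_bwd(dA, g1, contact, comb_idx, tcomb, e0, e1, c1, c2, c3,
                need_gates):
    """Gradients of :func:`combine_fwd` w.r.t. g1, tcomb, (e0, e1), gates."""
    B, N, _, H = g1.shape
    V = tcomb.shape[0]
    dg1 = np.empty_like(g1)
    dtcomb = np.zeros((V, H), dtype=g1.dtype)
    de0 = np.zeros(H, dtype=g1.dtype)
    de1 = np.zeros(H, dtype=g1.dtype)
    dc1 = np.zeros(B, dtype=g1.dtype)
    dc2 = np.zeros(B, dtype=g1.dtype)
    dc3 = np.zeros(B, dtype=g1.dtype)
    for b in range(B):
        for i in range(N):
            for j in range(N):
                ci = contact[b, i, j]
                t = comb_idx[b, i, j]
                for h in range(H):
                    g = dA[b, h, i, j]
                    dg1[b, i, j, h] = c1[b] * g
                    dtcomb[t, h] += c3[b] * g
                    de0[h] += -c2[b] * (1.0 - ci) * g
                    de1[h] += -c2[b] * ci * g
                    if need_gates:
                        g2 = ci * (e1[h] - e0[h]) + e0[h]
                        dc1[b] += g1[b, i, j, h] * g
                        dc2[b] += -g2 * g
                        dc3[b] += tcomb[t, h] * g
    return dg1, dtcomb, de0, de1, dc1, dc2, dc3


@njit(cache=True, fastmath=True)
def softmax_fwd(A, kmask):
    """Row softmax over the key axis restricted to valid keys.

    ``A`` is (B, H, N, N); ``kmask`` is (B, N) over keys.  Rows without any
    valid key fall back to the uniform distribution over all N keys.
    """
    B, H, N, _ = A.shape
    P = np.empty_like(A)
    for b in range(B):
        nv = 0
        for j in range(N):
            if kmask[b, j]:
                nv += 1
        if nv == N:  # branch-free fast path (fully valid selection)
            for h in range(H):
                for i in range(N):
                    m = A[b, h, i, 0]
                    for j in range(1, N):
                        if A[b, h, i, j] > m:
                            m = A[b, h, i, j]
                    s = 0.0
                    for j in range(N):
                        e = np.exp(A[b, h, i, j] - m)
                        P[b, h, i, j] = e
                        s += e
                    inv = 1.0 / s
                    for j in range(N):
                        P[b, h, i, j] *= inv
            continue
        for h in range(H):
            for i in range(N):
                if nv == 0:
                    for j in range(N):
                        P[b, h, i, j] = 1.0 / N
                    continue
                m = -np.inf
                for j in range(N):
                    if kmask[b, j] and A[b, h, i, j] > m:
                        m = A[b, h, i, j]
                s = 0.0
                for j in range(N):
                    if kmask[b, j]:
                        e = np.exp(A[b, h, i, j] - m)
                        P[b, h, i, j] = e
                        s += e
                    else:
                        P[b, h, i, j] = 0.0
                inv = 1.0 / s
                for j in range(N):
                    P[b, h, i, j] *= inv
    return P


@njit(cache=True, fastmath=True)
def bsa_fwd(P, anchors, R, origins, eps):
    """Side-chain geometric code (B, N, 7H) from attention and anchors.

    Per head: project anchors with the attention rows, express the point in
    the residue frame (g = Rᵀ(fm - origin)), and emit (ξ=g, ζ=|g|,
    ψ=g/(ζ+eps)).  Returns the code and the frame-local points g (saved
    for the backward pass).
    """
    B, H, N, _ = P.shape
    code = np.empty((B, N, 7 * H), dtype=P.dtype)
    gsave = np.empty((B, H, N, 3), dtype=P.dtype)
    for b in range(B):
        for h in range(H):
            for i in range(N):
                f0 = 0.0
                f1 = 0.0
                f2 = 0.0
                for j in range(N):
                    p = P[b, h, i, j]
                    f0 += p * anchors[b, j, 0]
                    f1 += p * anchors[b, j, 1]
                    f2 += p * anchors[b, j, 2]
                r0 = f0 - origins[b, i, 0]
                r1 = f1 - origins[b, i, 1]
                r2 = f2 - origins[b, i, 2]
                g0 = R[b, i, 0, 0] * r0 + R[b, i, 1, 0] * r1 + R[b, i, 2, 0] * r2
                g1 = R[b, i, 0, 1] * r0 + R[b, i, 1, 1] * r1 + R[b, i, 2, 1] * r2
                g2 = R[b, i, 0, 2] * r0 + R[b, i, 1, 2] * r1 + R[b, i, 2, 2] * r2
                gsave[b, h, i, 0] = g0
                gsave[b, h, i, 1] = g1
                gsave[b, h, i, 2] = g2
                zeta = np.sqrt(g0 * g0 + g1 * g1 + g2 * g2 + 1e-24)
                inv = 1.0 / (zeta + eps)
                o = 7 * h
                code[b, i, o] = g0
                code[b, i, o + 1] = g1
                code[b, i, o + 2] = g2
                code[b, i, o + 3] = zeta
                code[b, i, o + 4] = g0 * inv
                code[b, i, o + 5] = g1 * inv
                code[b, i, o + 6] = g2 * inv
    return code, gsave


@njit(cache=True, fastmath=True)
def bsa_bwd(dcode, gsave, P, anchors, R, eps):
    """Gradient of :func:`bsa_fwd` w.r.t. the attention weights P."""
    B, H, N, _ = P.shape
    dP = np.empty_like(P)
    for b in range(B):
        for h in range(H):
            o = 7 * h
            for i in range(N):
                g0 = gsave[b, h, i, 0]
                g1 = gsave[b, h, i, 1]
                g2 = gsave[b, h, i, 2]
                zeta = np.sqrt(g0 * g0 + g1 * g1 + g2 * g2 + 1e-24)
                inv = 1.0 / (zeta + eps)
                dxi0 = dcode[b, i, o]
                dxi1 = dcode[b, i, o + 1]
                dxi2 = dcode[b, i, o + 2]
                dz = dcode[b, i, o + 3]
                dp0 = dcode[b, i, o + 4]
                dp1 = dcode[b, i, o + 5]
                dp2 = dcode[b, i, o + 6]
                # ζ and ψ chain terms
                dot_pg = dp0 * g0 + dp1 * g1 + dp2 * g2
                coef = dz / zeta - dot_pg * inv * inv / zeta
                dg0 = dxi0 + coef * g0 + dp0 * inv
                dg1 = dxi1 + coef * g1 + dp1 * inv
                dg2 = dxi2 + coef * g2 + dp2 * inv
                # back through the frame: drel = R dg
                dr0 = R[b, i, 0, 0] * dg0 + R[b, i, 0, 1] * dg1 + R[b, i, 0, 2] * dg2
                dr1 = R[b, i, 1, 0] * dg0 + R[b, i, 1, 1] * dg1 + R[b, i, 1, 2] * dg2
                dr2 = R[b, i, 2, 0] * dg0 + R[b, i, 2, 1] * dg1 + R[b, i, 2, 2] * dg2
                for j in range(N):
                    dP[b, h, i, j] = (dr0 * anchors[b, j, 0]
                                      + dr1 * anchors[b, j, 1]
                                      + dr2 * anchors[b, j, 2])
    return dP


@njit(cache=True, fastmath=True)
def softmax_bwd(dP, P, kmask):
    """dA = P * (dP - Σ_j dP P) with zero gradient on fallback rows."""
    B, H, N, _ = P.shape
    dA = np.empty_like(P)
    for b in range(B):
        nv = 0
        for j in range(N):
            if kmask[b, j]:
                nv += 1
        for h in range(H):
            for i in range(N):
                if nv == 0:
                    for j in range(N):
                        dA[b, h, i, j] = 0.0
                    continue
                inner = 0.0
                for j in range(N):
                    inner += dP[b, h, i, j] * P[b, h, i, j]
                for j in range(N):
                    dA[b, h, i, j] = P[b, h, i, j] * (dP[b, h, i, j] - inner)
    return dA
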