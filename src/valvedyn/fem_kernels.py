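"""Numba element kernels for the leaflet FE assembly.

Per-element, per-quadrature-point evaluation of the fiber-reinforced
hyperelastic law (isochoric neo-Hooke + volumetric penalty + tension-only
exponential fibers), the internal force and the consistent material +
geometric tangent.  Falls back to the vectorized numpy path in ``fem.py``
when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard runtime dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True, fastmath=False)
def element_forces(ue, G, wdet, fib, c10, d1, k1, k2, want_K):
    """Element forces/stresses and (optionally) tangent matrices.

    Uses a mean-dilatation (B-bar) treatment of the volumetric term: the
    penalty pressure is driven by the element-average Jacobian, which
    removes the volumetric locking that displacement tetrahedra otherwise
    show at nu = 0.475 (the deviatoric and fiber parts stay pointwise).

    Returns (fe[E,10,3], S4[E,4,3,3], Ke[E,30,30], bad) where ``bad`` is
    nonzero if det(F) <= 0 (1) or the fiber exponent overflows (2).
    """
    E = ue.shape[0]
    fe = np.zeros((E, 10, 3))
    S4 = np.zeros((E, 4, 3, 3))
    Ke = np.zeros((E, 30, 30)) if want_K else np.zeros((1, 1, 1))
    Fq = np.empty((4, 3, 3))
    FiTq = np.empty((4, 3, 3))       # F^{-T} per qp
    Jq = np.empty(4)
    C = np.empty((3, 3))
    Ci = np.empty((3, 3))
    S = np.empty((3, 3))
    P = np.empty((3, 3))
    CC = np.empty((3, 3, 3, 3))
    A = np.empty((3, 3, 3, 3))
    T = np.empty((10, 3, 3, 3))
    gvec = np.empty(30)              # d(Ve * Jbar)/dd
    for e in range(E):
        a0x, a0y, a0z = fib[e, 0], fib[e, 1], fib[e, 2]
        ce, de, ke1, ke2 = c10[e], d1[e], k1[e], k2[e]
        av = (a0x, a0y, a0z)
        # --- pass 1: kinematics and element-average dilatation -----------
        ve = 0.0
        vbar = 0.0
        for q in range(4):
            w = wdet[e, q]
            ve += w
            for i in range(3):
                for J in range(3):
                    s = 1.0 if i == J else 0.0
                    for a in range(10):
                        s += ue[e, a, i] * G[e, q, a, J]
                    Fq[q, i, J] = s
            F = Fq[q]
            detF = (F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
                    - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
                    + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]))
            if detF <= 0.0:
                return fe, S4, Ke, 1
            Jq[q] = detF
            vbar += w * detF
            # F^{-T} = adj(F)^T / detF = cof(F) / detF
            FiTq[q, 0, 0] = (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1]) / detF
            FiTq[q, 0, 1] = (F[1, 2] * F[2, 0] - F[1, 0] * F[2, 2]) / detF
            FiTq[q, 0, 2] = (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]) / detF
            FiTq[q, 1, 0] = (F[0, 2] * F[2, 1] - F[0, 1] * F[2, 2]) / detF
            FiTq[q, 1, 1] = (F[0, 0] * F[2, 2] - F[0, 2] * F[2, 0]) / detF
            FiTq[q, 1, 2] = (F[0, 1] * F[2, 0] - F[0, 0] * F[2, 1]) / detF
            FiTq[q, 2, 0] = (F[0, 1] * F[1, 2] - F[0, 2] * F[1, 1]) / detF
            FiTq[q, 2, 1] = (F[0, 2] * F[1, 0] - F[0, 0] * F[1, 2]) / detF
            FiTq[q, 2, 2] = (F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]) / detF
        jbar = vbar / ve
        pbar = (2.0 / de) * (jbar - 1.0)     # dUvol/dJbar
        dpbar = 2.0 / de                     # d2Uvol/dJbar2
        # --- pass 2: stresses, forces, tangent ----------------------------
        if want_K:
            for r in range(30):
                gvec[r] = 0.0
        for q in range(4):
            w = wdet[e, q]
            F = Fq[q]
            FiT = FiTq[q]
            detF = Jq[q]
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for k in range(3):
                        s += F[k, i] * F[k, j]
                    C[i, j] = s
            for i in range(3):
                for j in range(3):
                    # Cinv = F^{-1} F^{-T} = (F^{-T})^T F^{-T}
                    s = 0.0
                    for k in range(3):
                        s += FiT[k, i] * FiT[k, j]
                    Ci[i, j] = s
            I1 = C[0, 0] + C[1, 1] + C[2, 2]
            J23 = detF ** (-2.0 / 3.0)
            I4 = 0.0
            for i in range(3):
                for j in range(3):
                    I4 += av[i] * C[i, j] * av[j]
            wf = I4 - 1.0
            expo = ke2 * wf * wf
            if expo > 60.0:
                return fe, S4, Ke, 2
            ew = np.exp(expo)
            gfib = 2.0 * ke1 * wf * ew if wf > 0.0 else 0.0
            hfib = (2.0 * ke1 * ew * (1.0 + 2.0 * ke2 * wf * wf)
                    if wf > 0.0 else 0.0)
            for i in range(3):
                for j in range(3):
                    eye = 1.0 if i == j else 0.0
                    S[i, j] = (2.0 * ce * J23 * (eye - (I1 / 3.0) * Ci[i, j])
                               + pbar * detF * Ci[i, j]
                               + gfib * av[i] * av[j])
            S4[e, q, :, :] = S
            for i in range(3):
                for J in range(3):
                    s = 0.0
                    for K_ in range(3):
                        s += F[i, K_] * S[K_, J]
                    P[i, J] = s
            for a in range(10):
                for i in range(3):
                    s = 0.0
                    for J in range(3):
                        s += P[i, J] * G[e, q, a, J]
                    fe[e, a, i] += w * s
            if not want_K:
                continue
            # gvec_ai += w J F^{-T}_{iJ} G_{aJ}  (for the pbar coupling)
            for a in range(10):
                for i in range(3):
                    s = 0.0
                    for J in range(3):
                        s += FiT[i, J] * G[e, q, a, J]
                    gvec[3 * a + i] += w * detF * s
            # material tangent CC = 2 dS/dC at fixed pbar
            t_iso = 2.0 * ce * J23
            for i in range(3):
                for j in range(3):
                    eij = 1.0 if i == j else 0.0
                    for k in range(3):
                        for l in range(3):
                            ekl = 1.0 if k == l else 0.0
                            sym = 0.5 * (Ci[i, k] * Ci[j, l]
                                         + Ci[i, l] * Ci[j, k])
                            iso = t_iso * (
                                -(1.0 / 3.0) * Ci[i, j] * ekl
                                + (I1 / 9.0) * Ci[i, j] * Ci[k, l]
                                - (1.0 / 3.0) * eij * Ci[k, l]
                                + (I1 / 3.0) * sym)
                            vol = pbar * detF * (
                                0.5 * Ci[i, j] * Ci[k, l] - sym)
                            fibt = hfib * av[i] * av[j] * av[k] * av[l]
                            CC[i, j, k, l] = 2.0 * (iso + vol + fibt)
            # A[i,I,j,J] = δ_ij S[I,J] + F[i,M] CC[M,I,J,L] F[j,L]
            for i in range(3):
                for I in range(3):
                    for j in range(3):
                        for J in range(3):
                            s = S[I, J] if i == j else 0.0
                            for M in range(3):
                                t = 0.0
                                for L in range(3):
                                    t += CC[M, I, J, L] * F[j, L]
                                s += F[i, M] * t
                            A[i, I, j, J] = s
            for a in range(10):
                for i in range(3):
                    for j in range(3):
                        for J in range(3):
                            s = 0.0
                            for I in range(3):
                                s += G[e, q, a, I] * A[i, I, j, J]
                            T[a, i, j, J] = s
            for a in range(10):
                for i in range(3):
                    ra = 3 * a + i
                    for b in range(10):
                        for j in range(3):
                            s = 0.0
                            for J in range(3):
                                s += T[a, i, j, J] * G[e, q, b, J]
                            Ke[e, ra, 3 * b + j] += w * s
        if want_K:
            # rank-one coupling from pbar(Jbar): (dpbar/Ve) g g^T
            coef = dpbar / ve
            for ra in range(30):
                gra = gvec[ra]
                if gra == 0.0:
                    continue
                for rb in range(30):
                    Ke[e, ra, rb] += coef * gra * gvec[rb]
    return fe, S4, Ke, 0
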