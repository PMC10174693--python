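"""Optional JIT-compiled kernel for the batched order-parameter RHS.

The numpy implementation in :mod:`doublering.meanfield` is the reference;
this kernel computes the same quantities with explicit loops and is used
automatically when numba is importable. Both paths are compared in the
test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is present in normal installs
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True, fastmath=False)
def _rhs_kernel(Y, U, j0, jsA, jsB, ja, phi_ext, chi, eta_a, eta_b, w_eta,
                cos_u, sin_u, tau, floor, out):
    B = Y.shape[0]
    S = eta_a.size
    n_u = cos_u.size
    pi = np.pi
    for ib in range(B):
        r0 = Y[ib, 0]
        rA = Y[ib, 1]
        rB = Y[ib, 2]
        psA = Y[ib, 3]
        psB = Y[ib, 4]
        r0A = Y[ib, 5]
        r0B = Y[ib, 6]
        C0 = U[ib, 0]
        CA = U[ib, 1]
        CB = U[ib, 2]
        eA = U[ib, 3]
        eB = U[ib, 4]
        # complex bump/input amplitudes per map
        zAx = jsA * rA * np.cos(psA) + eA * np.cos(phi_ext)
        zAy = jsA * rA * np.sin(psA) + eA * np.sin(phi_ext)
        zBx = (jsB * rB * np.cos(psB) + ja * rA * np.cos(psA)
               + eB * np.cos(phi_ext))
        zBy = (jsB * rB * np.sin(psB) + ja * rA * np.sin(psA)
               + eB * np.sin(phi_ext))
        absA = np.sqrt(zAx * zAx + zAy * zAy)
        absB = np.sqrt(zBx * zBx + zBy * zBy)
        phi1 = np.arctan2(zAy, zAx)
        phi2 = np.arctan2(zBy, zBx)
        delta = phi1 - phi2
        cd = np.cos(delta)
        sd = np.sin(delta)
        c1 = np.cos(phi1)
        s1 = np.sin(phi1)
        c2 = np.cos(phi2)
        s2 = np.sin(phi2)

        M0 = 0.0
        M0A = 0.0
        M0B = 0.0
        KAx = 0.0
        KAy = 0.0
        KBx = 0.0
        KBy = 0.0
        for s in range(S):
            a = eta_a[s]
            b = eta_b[s]
            p = a * absA
            q = b * absB
            S0 = C0 + j0 * r0 + CA * a + CB * b
            m0 = 0.0
            hc = 0.0
            hs = 0.0
            g0c = 0.0
            g0s = 0.0
            g1m = 0.0
            g2c = 0.0
            g2s = 0.0
            for iu in range(n_u):
                A = S0 + p * cos_u[iu]
                if q < 1e-300:
                    g0 = A if A > 0.0 else 0.0
                    g1 = 0.0
                    g2 = 0.0
                else:
                    cc = -A / q
                    if cc > 1.0:
                        cc = 1.0
                    elif cc < -1.0:
                        cc = -1.0
                    sc = np.sqrt(1.0 - cc * cc)
                    cang = np.arccos(cc)
                    g0 = (A * cang + q * sc) / pi
                    g1 = (A * sc + q * (cang + sc * cc) * 0.5) / pi
                    g2 = (A * sc * cc
                          + q * (sc + sc * (3.0 - 4.0 * sc * sc)
                                 / 3.0) * 0.5) / pi
                cos_ud = cos_u[iu] * cd - sin_u[iu] * sd
                h = g0 + chi * cos_ud * g1
                m0 += h
                hc += h * cos_u[iu]
                hs += h * sin_u[iu]
                g0c += g0 * cos_u[iu]
                g0s += g0 * sin_u[iu]
                g1m += g1
                g2c += g2 * cos_u[iu]
                g2s += g2 * sin_u[iu]
            inv = 1.0 / n_u
            m0 *= inv
            hc *= inv
            hs *= inv
            g0c *= inv
            g0s *= inv
            g1m *= inv
            g2c *= inv
            g2s *= inv
            # KA_atom = (hc + i hs) e^{i phi1}
            kax = hc * c1 - hs * s1
            kay = hc * s1 + hs * c1
            # KB_atom = (g1m + chi/2 (e^{i d}(g0c+ig0s) + e^{-i d}(g2c-ig2s)))
            #           * e^{i phi2}
            tx = g1m + 0.5 * chi * (cd * g0c - sd * g0s
                                    + cd * g2c - sd * g2s)
            ty = 0.5 * chi * (sd * g0c + cd * g0s - (sd * g2c + cd * g2s))
            kbx = tx * c2 - ty * s2
            kby = tx * s2 + ty * c2
            M0 += w_eta * m0
            M0A += w_eta * a * m0
            M0B += w_eta * b * m0
            KAx += w_eta * a * kax
            KAy += w_eta * a * kay
            KBx += w_eta * b * kbx
            KBy += w_eta * b * kby
        # project on the bump phases
        pAr = KAx * np.cos(psA) + KAy * np.sin(psA)
        pAi = KAy * np.cos(psA) - KAx * np.sin(psA)
        pBr = KBx * np.cos(psB) + KBy * np.sin(psB)
        pBi = KBy * np.cos(psB) - KBx * np.sin(psB)
        out[ib, 0] = (-r0 + M0) / tau
        out[ib, 1] = (-rA + pAr) / tau
        out[ib, 2] = (-rB + pBr) / tau
        out[ib, 3] = pAi / (tau * rA) if rA > floor else 0.0
        out[ib, 4] = pBi / (tau * rB) if rB > floor else 0.0
        out[ib, 5] = (-r0A + M0A) / tau
        out[ib, 6] = (-r0B + M0B) / tau
    return out
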