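"""Numba inner loops for the Gibbs samplers.

The marker sweeps consume pre-generated uniform/normal variates so that all
randomness stays in one seeded numpy Generator at the Python level; the
kernels are purely deterministic given their inputs.  Residual vectors are
updated incrementally after every effect move.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_univariate(WT, e, alpha, delta, c, s2a, s2e, log_prior_ratio,
                     u, z):
    """One spike-and-slab sweep over all markers (single trait).

    WT : (m, n) marker matrix transposed, C-contiguous
    e  : (n,) current residual y - Xb - W alpha, updated in place
    alpha, delta : (m,) current effects / inclusion indicators, in place
    c  : (m,) per-marker sum of squared covariates w_j'w_j
    log_prior_ratio : log((1-pi)/pi)
    u, z : (m,) uniforms / standard normals for this sweep

    Returns (n_included, sum of squared included effects).
    """
    m, n = WT.shape
    k = 0
    ssq = 0.0
    for j in range(m):
        cj = c[j]
        if cj <= 0.0:
            alpha[j] = 0.0
            delta[j] = 0
            continue
        r = cj * alpha[j]
        for i in range(n):
            r += WT[j, i] * e[i]
        v0 = cj * s2e
        v1 = cj * cj * s2a + v0
        log_bf = 0.5 * (math.log(v0) - math.log(v1)) \
            + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
        t = log_prior_ratio + log_bf
        if t > 35.0:
            p = 1.0
        elif t < -35.0:
            p = 0.0
        else:
            p = 1.0 / (1.0 + math.exp(-t))
        old = alpha[j]
        if u[j] < p:
            prec = cj / s2e + 1.0 / s2a
            mean = (r / s2e) / prec
            a = mean + z[j] / math.sqrt(prec)
            alpha[j] = a
            delta[j] = 1
            k += 1
            ssq += a * a
        else:
            alpha[j] = 0.0
            delta[j] = 0
        d = old - alpha[j]
        if d != 0.0:
            for i in range(n):
                e[i] += WT[j, i] * d
    return k, ssq


@njit(cache=True)
def sweep_bivariate(WT, E0, E1, alpha, cat, c,
                    Ri00, Ri01, Ri11,
                    Sa00, Sa01, Sa11,
                    lp0, lp1, lp2, lp3,
                    u, z, scatter):
    """One sweep of the two-trait spike-and-slab model.

    cat codes the inclusion category per marker: 0 = (0,0), 1 = (1,0),
    2 = (0,1), 3 = (1,1).  Ri* are entries of the residual precision
    Sigma_eps^{-1}; Sa* entries of the current Sigma_alpha; lp* the log
    prior probabilities of the four categories.  ``scatter`` (2x2)
    accumulates beta_j beta_j' over markers with at least one active trait,
    where the inactive-trait component is completed from its conditional
    prior; returns the count of such markers.
    """
    m, n = WT.shape
    detSa = Sa00 * Sa11 - Sa01 * Sa01
    # inverse of Sigma_alpha
    Ia00 = Sa11 / detSa
    Ia01 = -Sa01 / detSa
    Ia11 = Sa00 / detSa
    logdetSa = math.log(detSa)
    k = 0
    for j in range(m):
        cj = c[j]
        if cj <= 0.0:
            alpha[j, 0] = 0.0
            alpha[j, 1] = 0.0
            cat[j] = 0
            continue
        r0 = cj * alpha[j, 0]
        r1 = cj * alpha[j, 1]
        for i in range(n):
            r0 += WT[j, i] * E0[i]
            r1 += WT[j, i] * E1[i]
        b0 = Ri00 * r0 + Ri01 * r1
        b1 = Ri01 * r0 + Ri11 * r1

        # log marginal weights (beta integrated out), relative to (0,0)
        w0 = lp0
        P1 = cj * Ri00 + 1.0 / Sa00
        w1 = lp1 + 0.5 * b0 * b0 / P1 - 0.5 * math.log(Sa00) \
            - 0.5 * math.log(P1)
        P2 = cj * Ri11 + 1.0 / Sa11
        w2 = lp2 + 0.5 * b1 * b1 / P2 - 0.5 * math.log(Sa11) \
            - 0.5 * math.log(P2)
        Q00 = cj * Ri00 + Ia00
        Q01 = cj * Ri01 + Ia01
        Q11 = cj * Ri11 + Ia11
        detQ = Q00 * Q11 - Q01 * Q01
        # V = Q^{-1}; quad = b' V b
        quad = (Q11 * b0 * b0 - 2.0 * Q01 * b0 * b1 + Q00 * b1 * b1) / detQ
        w3 = lp3 + 0.5 * quad - 0.5 * logdetSa - 0.5 * math.log(detQ)

        mx = max(max(w0, w1), max(w2, w3))
        e0 = math.exp(w0 - mx)
        e1 = math.exp(w1 - mx)
        e2 = math.exp(w2 - mx)
        e3 = math.exp(w3 - mx)
        tot = e0 + e1 + e2 + e3
        uu = u[j] * tot
        old0 = alpha[j, 0]
        old1 = alpha[j, 1]
        be0 = 0.0
        be1 = 0.0
        if uu < e0:
            cat[j] = 0
            alpha[j, 0] = 0.0
            alpha[j, 1] = 0.0
        elif uu < e0 + e1:
            cat[j] = 1
            a0 = b0 / P1 + z[j, 0] / math.sqrt(P1)
            alpha[j, 0] = a0
            alpha[j, 1] = 0.0
            # inactive component from conditional prior given beta0 = a0
            cv = Sa11 - Sa01 * Sa01 / Sa00
            be0 = a0
            be1 = Sa01 / Sa00 * a0 + z[j, 1] * math.sqrt(cv)
        elif uu < e0 + e1 + e2:
            cat[j] = 2
            a1 = b1 / P2 + z[j, 1] / math.sqrt(P2)
            alpha[j, 0] = 0.0
            alpha[j, 1] = a1
            cv = Sa00 - Sa01 * Sa01 / Sa11
            be1 = a1
            be0 = Sa01 / Sa11 * a1 + z[j, 0] * math.sqrt(cv)
        else:
            cat[j] = 3
            V00 = Q11 / detQ
            V01 = -Q01 / detQ
            V11 = Q00 / detQ
            m0 = V00 * b0 + V01 * b1
            m1 = V01 * b0 + V11 * b1
            l00 = math.sqrt(V00)
            l10 = V01 / l00
            l11 = math.sqrt(max(V11 - l10 * l10, 1e-300))
            a0 = m0 + l00 * z[j, 0]
            a1 = m1 + l10 * z[j, 0] + l11 * z[j, 1]
            alpha[j, 0] = a0
            alpha[j, 1] = a1
            be0 = a0
            be1 = a1
        if cat[j] > 0:
            k += 1
            scatter[0, 0] += be0 * be0
            scatter[0, 1] += be0 * be1
            scatter[1, 1] += be1 * be1
        d0 = old0 - alpha[j, 0]
        d1 = old1 - alpha[j, 1]
        if d0 != 0.0 or d1 != 0.0:
            for i in range(n):
                E0[i] += WT[j, i] * d0
                E1[i] += WT[j, i] * d1
    scatter[1, 0] = scatter[0, 1]
    return k
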