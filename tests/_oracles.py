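"""Independent oracles used by the test suite.

These deliberately avoid the package's solver code paths: the subgradient
minimiser touches only the objective value, and the small helpers recompute
quantities by brute force (dense products, exhaustive prefix enumeration,
closed forms).
"""

from __future__ import annotations

import numpy as np
from numba import njit


def penalized_objective(tasks, phi, lam_s, lam_b, S, B):
    """Direct (non-cached) evaluation of the multitask objective."""
    J = 0.0
    d = len(tasks)
    for j, t in enumerate(tasks):
        w = S[:, j] + B[:, j]
        r = t.response - t.design.T @ w
        J += 0.5 * (r @ r) / t.n
    J += lam_s * np.sum(phi * np.abs(S))
    J += lam_b * np.sum(np.max(np.abs(B), axis=1))
    return J


@njit
def subgradient_minimize(gram, atx, xtx, nvec, phi, lam_s, lam_b, iters):
    """Plain subgradient descent on the joint objective; returns best value.

    Diminishing step sizes scaled by the smooth part's curvature; tracks the
    best objective seen.  Slow but free of proximal/thresholding machinery.
    """
    d, p, _ = gram.shape
    S = np.zeros((p, d))
    B = np.zeros((p, d))

    def value(S, B):
        J = 0.0
        for dd in range(d):
            rss = xtx[dd]
            for k in range(p):
                w = S[k, dd] + B[k, dd]
                if w != 0.0:
                    rss -= 2.0 * w * atx[dd, k]
                    for l in range(p):
                        wl = S[l, dd] + B[l, dd]
                        if wl != 0.0:
                            rss += w * wl * gram[dd, k, l]
            J += 0.5 * rss / nvec[dd]
            for k in range(p):
                J += lam_s * phi[k, dd] * abs(S[k, dd])
        for k in range(p):
            m = 0.0
            for dd in range(d):
                if abs(B[k, dd]) > m:
                    m = abs(B[k, dd])
            J += lam_b * m
        return J

    best = value(S, B)
    L = 0.0
    for dd in range(d):
        tr = 0.0
        for k in range(p):
            tr += gram[dd, k, k]
        if tr / nvec[dd] > L:
            L = tr / nvec[dd]
    step0 = 1.0 / max(L, 1e-8)
    for t in range(iters):
        gS = np.zeros((p, d))
        for dd in range(d):
            for k in range(p):
                acc = -atx[dd, k]
                for l in range(p):
                    w = S[l, dd] + B[l, dd]
                    if w != 0.0:
                        acc += w * gram[dd, k, l]
                gS[k, dd] = acc / nvec[dd]
        sgS = gS + lam_s * phi * np.sign(S)
        sgB = gS.copy()
        for k in range(p):
            m = 0.0
            for dd in range(d):
                if abs(B[k, dd]) > m:
                    m = abs(B[k, dd])
            if m > 0.0:
                for dd in range(d):
                    if abs(B[k, dd]) == m:
                        sgB[k, dd] += lam_b * np.sign(B[k, dd])
                        break
        eta = step0 / np.sqrt(t + 1.0)
        S = S - eta * sgS
        B = B - eta * sgB
        val = value(S, B)
        if val < best:
            best = val
    return best


def aupr_by_prefix_enumeration(ranked_pairs, gold_pairs):
    """Step-rule AUPR computed by exhaustive prefix enumeration."""
    tp = 0
    prev_rec = 0.0
    area = 0.0
    npos = len(gold_pairs)
    for i, e in enumerate(ranked_pairs, start=1):
        if e in gold_pairs:
            tp += 1
        rec = tp / npos
        area += (tp / i) * (rec - prev_rec)
        prev_rec = rec
    return area
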