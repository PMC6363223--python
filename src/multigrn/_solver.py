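"""Numba kernels for the sparse + block-sparse multitask solver.

Per gene the coefficient matrix ``W`` (TFs x datasets) is decomposed into a
dataset-specific elementwise-sparse part ``S`` (l1/l1 penalty, weighted by
the adaptive-prior matrix ``Phi``) and a shared row-sparse part ``B``
(l1/l-inf penalty).  The objective minimised is

    J(S, B) = sum_d  1/(2 n_d) || X^(d) - A^(d)T (S+B)[:, d] ||^2
              + lambda_s * sum_{k,d} Phi[k,d] |S[k,d]|
              + lambda_b * sum_k max_d |B[k,d]|

which is jointly convex.  It is solved by cyclical coordinate descent with
covariance updates: only the Gram products ``A A^T`` (per task) and
``A X^T`` are touched inside the sweeps, so they are precomputed once and
shared across genes, penalty-grid points and sweeps.

All kernels release the GIL so per-gene parallelism can use threads and
remain bit-identical to serial execution.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: machine-epsilon floor applied to residual sums of squares inside EBIC
#: (noise-free fits otherwise yield ln 0)
RSS_FLOOR = 2.220446049250313e-16


@njit(cache=True, nogil=True, inline="always")
def _soft(x, t):
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True, nogil=True)
def _linf_prox_row(v, c, lam_b, out):
    """Minimise sum_d c_d/2 * b_d^2 - v_d * b_d + lam_b * max_d |b_d|.

    Solved exactly through the dual: b = (v - z) / c where z is the
    weighted-l2 projection of v onto the l1 ball of radius lam_b,
    z_d = sign(v_d) * max(|v_d| - theta * c_d, 0) with theta >= 0 the root of
    the piecewise-linear equation sum_d (|v_d| - theta c_d)_+ = lam_b.
    For equal c this is the Moreau decomposition of the l-inf norm prox; for
    d = 1 it reduces to scalar soft-thresholding.  Coordinates with c_d = 0
    (zero-variance predictor in that task) are pinned to 0.
    """
    d = v.shape[0]
    sv = 0.0
    for i in range(d):
        if c[i] > 0.0:
            sv += abs(v[i])
    if sv <= lam_b:
        for i in range(d):
            out[i] = 0.0
        return
    # breakpoints of f(theta) = sum (|v_i| - theta c_i)_+
    tb = np.empty(d)
    nact = 0
    for i in range(d):
        if c[i] > 0.0:
            tb[nact] = abs(v[i]) / c[i]
            nact += 1
    if nact == 0:
        for i in range(d):
            out[i] = 0.0
        return
    t_sorted = np.sort(tb[:nact])
    # locate the segment where f crosses lam_b
    theta0 = 0.0
    for j in range(nact):
        f = 0.0
        for i in range(d):
            if c[i] > 0.0:
                r = abs(v[i]) - t_sorted[j] * c[i]
                if r > 0.0:
                    f += r
        if f <= lam_b:
            break
        theta0 = t_sorted[j]
    # on (theta0, next breakpoint] the active set is {i : |v_i|/c_i > theta0}
    sv_a = 0.0
    sc_a = 0.0
    for i in range(d):
        if c[i] > 0.0 and abs(v[i]) / c[i] > theta0:
            sv_a += abs(v[i])
            sc_a += c[i]
    if sc_a <= 0.0:
        theta = theta0
    else:
        theta = (sv_a - lam_b) / sc_a
        if theta < theta0:
            theta = theta0
    for i in range(d):
        if c[i] <= 0.0:
            out[i] = 0.0
        else:
            zi = abs(v[i]) - theta * c[i]
            if zi < 0.0:
                zi = 0.0
            if v[i] < 0.0:
                zi = -zi
            out[i] = (v[i] - zi) / c[i]


@njit(cache=True, nogil=True)
def _sweep(gram, atx, nvec, phi, lam_s, lam_b, use_b, active, S, B):
    """One full cyclical pass over all S entries then all B rows.

    Returns the largest absolute coefficient change of the pass.
    """
    d = gram.shape[0]
    p = gram.shape[1]
    maxdelta = 0.0
    # --- S entries: prior-weighted elementwise soft-thresholding -----------
    for k in range(p):
        if not active[k]:
            continue
        for dd in range(d):
            g = gram[dd, k, k]
            if g <= 0.0:
                continue
            acc = 0.0
            for l in range(p):
                w = S[l, dd] + B[l, dd]
                if w != 0.0:
                    acc += w * gram[dd, l, k]
            alpha = atx[dd, k] - acc + S[k, dd] * g
            new = _soft(alpha, nvec[dd] * phi[k, dd] * lam_s) / g
            delta = abs(new - S[k, dd])
            if delta > maxdelta:
                maxdelta = delta
            S[k, dd] = new
    # --- B rows: l-inf proximal update --------------------------------------
    if use_b:
        v = np.empty(d)
        c = np.empty(d)
        row = np.empty(d)
        for k in range(p):
            if not active[k]:
                continue
            for dd in range(d):
                g = gram[dd, k, k]
                if g <= 0.0:
                    v[dd] = 0.0
                    c[dd] = 0.0
                    continue
                acc = 0.0
                for l in range(p):
                    w = S[l, dd] + B[l, dd]
                    if w != 0.0:
                        acc += w * gram[dd, l, k]
                alpha = atx[dd, k] - acc + B[k, dd] * g
                v[dd] = alpha / nvec[dd]
                c[dd] = g / nvec[dd]
            _linf_prox_row(v, c, lam_b, row)
            for dd in range(d):
                delta = abs(row[dd] - B[k, dd])
                if delta > maxdelta:
                    maxdelta = delta
                B[k, dd] = row[dd]
    return maxdelta


@njit(cache=True, nogil=True)
def _fit(gram, atx, nvec, phi, lam_s, lam_b, use_b, active, S, B,
         tol, max_sweeps):
    """Run coordinate-descent sweeps to convergence; returns sweep count."""
    sweeps = 0
    while sweeps < max_sweeps:
        delta = _sweep(gram, atx, nvec, phi, lam_s, lam_b, use_b, active, S, B)
        sweeps += 1
        if delta < tol:
            break
    return sweeps


@njit(cache=True, nogil=True)
def _objective(gram, atx, xtx, nvec, phi, lam_s, lam_b, S, B):
    """The convex objective J(S, B); used for convergence diagnostics."""
    d = gram.shape[0]
    p = gram.shape[1]
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
            a = abs(B[k, dd])
            if a > m:
                m = a
        J += lam_b * m
    return J


@njit(cache=True, nogil=True, inline="always")
def _ln_binom(n, k):
    return (math.lgamma(n + 1.0) - math.lgamma(k + 1.0)
            - math.lgamma(n - k + 1.0))


@njit(cache=True, nogil=True)
def _ebic(gram, atx, xtx, nvec, dfvec, S, B, gamma, p_total):
    """Extended BIC averaged over tasks.

    EBIC = 1/d * sum_d [ n_d ln(RSS_d / n_d) + k_d ln n_d
                          + 2 gamma ln C(p*d, k_d) ]
    with k_d the support size of W[:, d] and p*d the joint predictor space
    spanned by the tasks; gamma = 0 recovers the ordinary BIC.  A saturated
    model has no residual degrees of freedom and its likelihood term
    degenerates, so it is never selectable: the criterion returns +inf when
    k_d >= dfvec[d], where dfvec holds the number of distinct conditions in
    each task (n_d without resampling; smaller under bootstrap resampling,
    where duplicated columns let a model with k >= #distinct interpolate
    exactly).
    """
    d = gram.shape[0]
    p = gram.shape[1]
    total = 0.0
    for dd in range(d):
        rss = xtx[dd]
        k_d = 0
        for k in range(p):
            w = S[k, dd] + B[k, dd]
            if w != 0.0:
                k_d += 1
                rss -= 2.0 * w * atx[dd, k]
                for l in range(p):
                    wl = S[l, dd] + B[l, dd]
                    if wl != 0.0:
                        rss += w * wl * gram[dd, k, l]
        if rss < RSS_FLOOR:
            rss = RSS_FLOOR
        n = nvec[dd]
        if k_d >= dfvec[dd]:
            return np.inf
        total += (n * math.log(rss / n) + k_d * math.log(n)
                  + 2.0 * gamma * _ln_binom(p_total * d, k_d))
    return total / d


@njit(cache=True, nogil=True)
def _select(gram, atx, xtx, nvec, dfvec, phi, lam_s_path, lam_b_path, gamma,
            use_b, active, tol, max_sweeps):
    """Fit a penalty path with warm starts and pick the EBIC minimiser.

    The path must be ordered from most to least penalised; ties in EBIC keep
    the earlier (sparser, more penalised) fit.  Returns
    (best_S, best_B, best_index, best_ebic, total_sweeps).
    """
    d = gram.shape[0]
    p = gram.shape[1]
    m = lam_s_path.shape[0]
    S = np.zeros((p, d))
    B = np.zeros((p, d))
    best_S = np.zeros((p, d))
    best_B = np.zeros((p, d))
    best_idx = -1
    best_val = np.inf
    total_sweeps = 0
    for i in range(m):
        total_sweeps += _fit(gram, atx, nvec, phi, lam_s_path[i],
                             lam_b_path[i], use_b, active, S, B,
                             tol, max_sweeps)
        val = _ebic(gram, atx, xtx, nvec, dfvec, S, B, gamma, p)
        if val < best_val - 1e-12:
            best_val = val
            best_idx = i
            for k in range(p):
                for dd in range(d):
                    best_S[k, dd] = S[k, dd]
                    best_B[k, dd] = B[k, dd]
    return best_S, best_B, best_idx, best_val, total_sweeps
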