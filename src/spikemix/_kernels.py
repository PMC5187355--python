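"""Numba kernels for the hot loops: trial simulation and the dip statistic.

Both kernels are deterministic pure functions; all randomness is drawn
outside (NumPy generators) and passed in, so reproducibility is governed
entirely by seed handling in the calling code.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_bernoulli(u, rates, gamma0, gammas, dt_ms):
    """Sample spike indicator matrices bin by bin with history feedback.

    Parameters
    ----------
    u:
        Pre-drawn uniforms, shape (n_trials, n_bins).
    rates:
        Base rate per trial (spikes/s), shape (n_trials,).
    gamma0, gammas:
        Trend (per ms) and spike-history weights.
    dt_ms:
        Bin width in ms.

    Each bin spikes with probability ``clamp(lambda * dt, 0, 1 - 1e-12)``
    where ``lambda = r * exp(gamma0 * t + sum_i gamma_i * dN_{t-i dt})``;
    emitted spikes feed back into the history of later bins.  Returns the
    int8 indicator matrix and the number of clamped bins (a clamp signals
    a rate/units misconfiguration when frequent).
    """
    n_tr, n_bins = u.shape
    m = gammas.size
    spikes = np.zeros((n_tr, n_bins), dtype=np.int8)
    n_clamped = 0
    dt_s = dt_ms * 1e-3
    for j in range(n_tr):
        r = rates[j]
        for n in range(n_bins):
            h = 0.0
            for i in range(1, m + 1):
                if n - i >= 0 and spikes[j, n - i] == 1:
                    h += gammas[i - 1]
            lam = r * np.exp(gamma0 * n * dt_ms + h)
            p = lam * dt_s
            if p > 1.0 - 1e-12:
                p = 1.0 - 1e-12
                n_clamped += 1
            if u[j, n] < p:
                spikes[j, n] = 1
    return spikes, n_clamped


@njit(cache=True)
def dip_sorted(x):
    """Hartigan & Hartigan's dip statistic of a sorted sample.

    Maximum distance between the empirical CDF and the closest unimodal
    CDF, computed by the classical iterative greatest-convex-minorant /
    least-concave-majorant algorithm.  ``x`` must be ascending.  Returns 0
    for a degenerate (constant) sample; the smallest attainable value for
    a nondegenerate sample is ``1 / (2 n)``.
    """
    n = x.shape[0]
    if n < 1:
        return 0.0
    if x[n - 1] == x[0]:
        return 0.0
    if n < 4:
        return 1.0 / (2.0 * n)

    # 1-based copies to keep the classical index arithmetic intact.
    X = np.empty(n + 1)
    for i in range(n):
        X[i + 1] = x[i]
    mn = np.zeros(n + 1, dtype=np.int64)
    mj = np.zeros(n + 1, dtype=np.int64)
    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)

    # Greatest convex minorant / least concave majorant predecessor maps.
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 1:
                break
            mnmnj = mn[mnj]
            if (X[j] - X[mnj]) * (mnj - mnmnj) < (X[mnj] - X[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n:
                break
            mjmjk = mj[mjk]
            if (X[k] - X[mjk]) * (mjk - mjmjk) < (X[mjk] - X[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low = 1
    high = n
    dip = 1.0  # in count units; divided by 2n on return
    iter_guard = 0
    while True:
        iter_guard += 1
        if iter_guard > n + 2:
            break  # defensive; the interval [low, high] shrinks every pass

        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = i
        l_gcm = i
        ix = ig - 1

        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = i
        l_lcm = i
        iv = 2

        # Maximum distance d between the minorant and the majorant.
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (X[lcmiv] - X[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (X[gcmix] - X[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (X[gcmix] - X[lcmiv1]) * (lcmiv - lcmiv1) / (
                        X[lcmiv] - X[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # Dip within the current minorant/majorant fits.
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and X[je] != X[jb]:
                C = (je - jb) / (X[je] - X[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (X[jj] - X[jb]) * C
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and X[je] != X[jb]:
                C = (je - jb) / (X[je] - X[jb])
                for jj in range(jb, je + 1):
                    t = (X[jj] - X[jb]) * C - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_u if dip_u > dip_l else dip_l
        if dip < dipnew:
            dip = dipnew
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


@njit(cache=True)
def dip_many(xs):
    """Dip statistic of each row of a matrix of sorted samples."""
    B = xs.shape[0]
    out = np.empty(B)
    for b in range(B):
        out[b] = dip_sorted(xs[b])
    return out
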