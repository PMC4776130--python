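"""Numba-compiled Monte Carlo kernels.

The hot loops (single-site Metropolis flips over millions of sweeps) live
here; the public sampler API in :mod:`phtmd.samplers` prepares the flat
arrays and wraps the outputs.  Flip energetics: for a flip of site i with
delta = 1 - 2 d_i,

    dE / ln10 = delta * (b_i - pH - sum_j W_ij (cp_j - d_j))

with b_i = pKa_ref_i - g_i absorbing the static perturber field g_i.
Each kernel seeds numba's internal RNG, so runs are reproducible per seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LN10 = math.log(10.0)


@njit(cache=True)
def _sweep(d, b, W, cp, ph, order):
    n = d.shape[0]
    # Fisher-Yates shuffle of the site visit order
    for i in range(n - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        order[i], order[j] = order[j], order[i]
    for k in range(n):
        i = order[k]
        s = 0.0
        for j in range(n):
            s += W[i, j] * (cp[j] - d[j])
        delta = 1.0 - 2.0 * d[i]
        de = LN10 * delta * (b[i] - ph - s)
        if de <= 0.0 or np.random.random() < math.exp(-de):
            d[i] = 1 - d[i]


@njit(cache=True)
def phtmd_ramp(d0, b, W, cp, phs, sweeps_per_window, record_every, seed):
    """Consecutive constant-pH windows with state handoff between windows.

    Returns (samples, finals): samples has shape
    (n_windows, sweeps_per_window // record_every, n_sites) uint8, finals
    (n_windows, n_sites) uint8.
    """
    np.random.seed(seed)
    n = d0.shape[0]
    nw = phs.shape[0]
    nrec = sweeps_per_window // record_every
    samples = np.empty((nw, nrec, n), dtype=np.uint8)
    finals = np.empty((nw, n), dtype=np.uint8)
    d = d0.copy()
    order = np.arange(n)
    for w in range(nw):
        ph = phs[w]
        rec = 0
        for t in range(sweeps_per_window):
            _sweep(d, b, W, cp, ph, order)
            if (t + 1) % record_every == 0 and rec < nrec:
                for i in range(n):
                    samples[w, rec, i] = d[i]
                rec += 1
        for i in range(n):
            finals[w, i] = d[i]
    return samples, finals


@njit(cache=True)
def phremd(d0s, b, W, cp, phs, sweeps_total, exchange_interval, record_every, seed):
    """pH replica exchange with alternating even/odd neighbour swaps.

    A swap between replicas a (pH_a, state s_a) and b (pH_b, s_b) is
    accepted with probability min(1, 10^{(pH_a - pH_b) (D(s_b) - D(s_a))})
    where D(s) is the total deprotonation count, the pH-coupled part of
    the energy.  Returns (samples, attempts, accepts).
    """
    np.random.seed(seed)
    nrep = d0s.shape[0]
    n = d0s.shape[1]
    nrec = sweeps_total // record_every
    samples = np.empty((nrep, nrec, n), dtype=np.uint8)
    d = d0s.copy()
    order = np.arange(n)
    attempts = 0
    accepts = 0
    swap_round = 0
    rec = 0
    for t in range(sweeps_total):
        for r in range(nrep):
            _sweep(d[r], b, W, cp, phs[r], order)
        if (t + 1) % record_every == 0 and rec < nrec:
            for r in range(nrep):
                for i in range(n):
                    samples[r, rec, i] = d[r, i]
            rec += 1
        if exchange_interval > 0 and (t + 1) % exchange_interval == 0:
            start = swap_round % 2
            swap_round += 1
            for a in range(start, nrep - 1, 2):
                bb = a + 1
                da = 0
                db = 0
                for i in range(n):
                    da += d[a, i]
                    db += d[bb, i]
                attempts += 1
                logp = LN10 * (phs[a] - phs[bb]) * (db - da)
                if logp >= 0.0 or np.random.random() < math.exp(logp):
                    accepts += 1
                    for i in range(n):
                        tmp = d[a, i]
                        d[a, i] = d[bb, i]
                        d[bb, i] = tmp
    return samples, attempts, accepts
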