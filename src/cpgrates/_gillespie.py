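"""Event-driven (Gillespie) kernel for context-dependent sequence evolution.

Single-nucleotide GTR rates plus a CpG-context multiplier: a C whose right
neighbour is G (and, in strand-symmetric mode, a G whose left neighbour is
C) has its transition rate scaled by ``lam_ts`` and its transversion rates
by ``lam_tv``.  Contexts are re-evaluated after every event, so the process
is exact — no time discretization.

Bases are encoded 0..3 = A, C, G, T.  The rate bookkeeping uses per-site
rates with block partial sums for O(block) event sampling and O(1) local
updates; block and total sums are periodically rebuilt to bound float
drift.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BS = 64  # block size for partial sums


@njit(cache=False)
def _site_rate(seq, i, L, q, lam_ts, lam_tv, sym):
    b = seq[i]
    r = q[b, 0] + q[b, 1] + q[b, 2] + q[b, 3]
    if b == 1:  # C with right-neighbour G
        if i + 1 < L and seq[i + 1] == 2:
            r += q[1, 3] * (lam_ts - 1.0) + (q[1, 0] + q[1, 2]) * (lam_tv - 1.0)
    elif b == 2 and sym:  # G with left-neighbour C (written-strand view of CpG)
        if i > 0 and seq[i - 1] == 1:
            r += q[2, 0] * (lam_ts - 1.0) + (q[2, 3] + q[2, 1]) * (lam_tv - 1.0)
    return r


@njit(cache=False)
def _target_rates(seq, i, L, q, lam_ts, lam_tv, sym, out):
    b = seq[i]
    for t in range(4):
        out[t] = q[b, t]
    if b == 1 and i + 1 < L and seq[i + 1] == 2:
        out[3] *= lam_ts
        out[0] *= lam_tv
        out[2] *= lam_tv
    elif b == 2 and sym and i > 0 and seq[i - 1] == 1:
        out[0] *= lam_ts
        out[3] *= lam_tv
        out[1] *= lam_tv


@njit(cache=False)
def gillespie_kernel(seq, q, lam_ts, lam_tv, sym, t0, t_max, seed,
                     ev_site, ev_time, ev_from, ev_to, ev_ctx):
    """Evolve ``seq`` in place from time ``t0`` to ``t_max``.

    Events are recorded into the ``ev_*`` buffers when they have nonzero
    capacity.  Returns ``(n_events, t_reached, full)``; ``full == 1`` means
    the buffers filled and the caller should resume from ``t_reached`` with
    larger buffers (the waiting-time draw had not yet been made, so
    resuming is distributionally exact).
    """
    np.random.seed(seed)
    L = seq.size
    nb = (L + _BS - 1) // _BS
    rates = np.empty(L)
    for i in range(L):
        rates[i] = _site_rate(seq, i, L, q, lam_ts, lam_tv, sym)
    bsum = np.zeros(nb)
    for i in range(L):
        bsum[i // _BS] += rates[i]
    total = 0.0
    for bi in range(nb):
        total += bsum[bi]

    t = t0
    nev = 0
    cap = ev_site.size
    tr = np.empty(4)
    while True:
        if cap > 0 and nev >= cap:
            return nev, t, 1
        if total <= 1e-300:
            break
        dt = -np.log(np.random.random()) / total
        if t + dt >= t_max:
            break
        t += dt

        # pick a site proportional to its rate: block scan, then in-block scan
        target = np.random.random() * total
        acc = 0.0
        bidx = nb - 1
        for bi in range(nb):
            if acc + bsum[bi] > target:
                bidx = bi
                break
            acc += bsum[bi]
        hi = bidx * _BS + _BS
        if hi > L:
            hi = L
        i = hi - 1
        for j in range(bidx * _BS, hi):
            if acc + rates[j] > target:
                i = j
                break
            acc += rates[j]

        _target_rates(seq, i, L, q, lam_ts, lam_tv, sym, tr)
        ti = tr[0] + tr[1] + tr[2] + tr[3]
        v = np.random.random() * ti
        to = 3
        acc2 = 0.0
        for tb in range(4):
            if acc2 + tr[tb] > v:
                to = tb
                break
            acc2 += tr[tb]
        frm = seq[i]
        ctx = 0
        if frm == 1 and i + 1 < L and seq[i + 1] == 2:
            ctx = 1
        elif frm == 2 and i > 0 and seq[i - 1] == 1:
            ctx = 2
        if cap > 0:
            ev_site[nev] = i
            ev_time[nev] = t
            ev_from[nev] = frm
            ev_to[nev] = to
            ev_ctx[nev] = ctx
        nev += 1
        seq[i] = to

        lo = i - 1 if i > 0 else 0
        hi2 = i + 2 if i + 2 <= L else L
        for j in range(lo, hi2):
            old = rates[j]
            new = _site_rate(seq, j, L, q, lam_ts, lam_tv, sym)
            rates[j] = new
            bsum[j // _BS] += new - old
            total += new - old

        if (nev & 4095) == 0:
            total = 0.0
            for bi in range(nb):
                total += bsum[bi]
        if (nev & 65535) == 0:
            for bi in range(nb):
                bsum[bi] = 0.0
            for i2 in range(L):
                bsum[i2 // _BS] += rates[i2]
    return nev, t_max, 0
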