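"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (direct
enumeration, matrix exponentials via scipy.linalg.expm, normal equations,
naive window scans) and never calls the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def gtr_q(exch, pi):
    """Rate matrix from six exchangeabilities (AC,AG,AT,CG,CT,GT) and
    stationary frequencies, normalized to unit expected rate."""
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    q = np.zeros((4, 4))
    for s, (i, j) in zip(exch, pairs):
        q[i, j] = s * pi[j]
        q[j, i] = s * pi[i]
    for i in range(4):
        q[i, i] = -q[i].sum()
    return q / -(np.asarray(pi) * np.diag(q)).sum()


def enumeration_loglik(h, r, m, exch, pi, t_h, t_r, t_m):
    """Log-likelihood of the 3-leaf star by summing over the four ancestor
    states per column with expm transition matrices."""
    q = gtr_q(exch, pi)
    ph, pr, pm = expm(q * t_h), expm(q * t_r), expm(q * t_m)
    total = 0.0
    for hh, rr, mm in zip(h, r, m):
        if hh > 3 or rr > 3 or mm > 3:
            continue
        site = sum(pi[a] * ph[a, hh] * pr[a, rr] * pm[a, mm] for a in range(4))
        total += np.log(site)
    return total


def enumeration_posterior(h, r, m, exch, pi, t_h, t_r, t_m):
    """Per-column ancestor posterior by Bayes' rule over the four states."""
    q = gtr_q(exch, pi)
    ph, pr, pm = expm(q * t_h), expm(q * t_r), expm(q * t_m)
    out = np.full((len(h), 4), np.nan)
    for i, (hh, rr, mm) in enumerate(zip(h, r, m)):
        if hh > 3 or rr > 3 or mm > 3:
            continue
        w = np.array([pi[a] * ph[a, hh] * pr[a, rr] * pm[a, mm] for a in range(4)])
        out[i] = w / w.sum()
    return out


def irls_binomial(x, events, sites, max_iter=100, tol=1e-12):
    """Binomial-logit IRLS from the weighted normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(events, float) / np.asarray(sites, float)
    n = np.asarray(sites, float)
    beta = np.zeros(x.shape[1])
    dev_old = np.inf
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = n * mu * (1.0 - mu)
        z = eta + (y - mu) / (mu * (1.0 - mu))
        xtw = x.T * w
        beta = np.linalg.solve(xtw @ x, xtw @ z)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0) + np.where(
                y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0
            )
        dev = 2.0 * float((n * term).sum())
        if abs(dev_old - dev) < tol * (abs(dev) + 1.0):
            break
        dev_old = dev
    return beta, dev


def ols_normal_equations(x, y):
    """(X'X)^{-1} X'y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return np.linalg.solve(x.T @ x, x.T @ y)


def spearman_brute(x, y):
    """Average-rank Spearman via rank-then-Pearson."""

    def avg_ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def _window_stats(s, i, j):
    sub = s[i:j]
    ok = [c for c in sub if c in "ACGT"]
    n = len(ok)
    if n == 0:
        return 0.0, 0.0
    nc = sum(c == "C" for c in ok)
    ng = sum(c == "G" for c in ok)
    gc = (nc + ng) / n
    pairs = [(sub[k], sub[k + 1]) for k in range(len(sub) - 1)
             if sub[k] in "ACGT" and sub[k + 1] in "ACGT"]
    if not pairs or nc == 0 or ng == 0:
        return gc, 0.0
    pcg = sum(a == "C" and b == "G" for a, b in pairs) / len(pairs)
    return gc, pcg / ((nc / n) * (ng / n))


def cgi_brute(s, min_length=200, min_gc=0.5, min_oe=0.6, window=200):
    """Naive sliding-window CGI caller: qualify each window, merge
    overlapping qualifiers, re-check merged regions."""
    L = len(s)
    qual = []
    for i in range(0, L - window + 1):
        sub = s[i : i + window]
        if any(c not in "ACGT" for c in sub):
            continue
        gc, oe = _window_stats(s, i, i + window)
        if gc >= min_gc and oe >= min_oe:
            qual.append((i, i + window))
    merged = []
    for iv in qual:
        if merged and iv[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
        else:
            merged.append(iv)
    out = []
    for i, j in merged:
        if j - i < min_length:
            continue
        gc, oe = _window_stats(s, i, j)
        if gc >= min_gc and oe >= min_oe:
            out.append((i, j))
    return out


def total_rate_brute(seq, exch, pi, lam_ts, lam_tv, sym=True):
    """Total leaving rate of a sequence state under the context model,
    computed site by site with explicit neighbour checks."""
    q = gtr_q(exch, pi)
    codes = [_CODE[c] for c in seq] if isinstance(seq, str) else list(seq)
    L = len(codes)
    total = 0.0
    for i, b in enumerate(codes):
        for to in range(4):
            if to == b:
                continue
            rate = q[b, to]
            if b == 1 and i + 1 < L and codes[i + 1] == 2:  # C of CpG
                if to == 3:
                    rate *= lam_ts
                else:
                    rate *= lam_tv
            elif b == 2 and sym and i > 0 and codes[i - 1] == 1:  # G of CpG
                if to == 0:
                    rate *= lam_ts
                else:
                    rate *= lam_tv
            total += rate
    return total
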