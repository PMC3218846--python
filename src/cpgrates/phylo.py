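"""GTR likelihood and marginal ancestral reconstruction on the fixed
((human, rhesus), mouse) topology.

The model is the general time-reversible (GTR) nucleotide substitution
model with no within-intron rate variation.  Because GTR is reversible the
unrooted three-leaf star can be rooted at the internal node, which is the
common ancestor of human and rhesus; the three branch lengths are the
human, rhesus and (root-to-)mouse paths in expected substitutions per site.
Likelihoods are computed by Felsenstein pruning over site patterns;
ancestral reconstruction is marginal (per-site posterior over the four
bases at the internal node given all three leaves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import minimize

from cpgrates.alignments import BASES, TripletAlignment, seq_to_codes

#: order of the six symmetric exchangeabilities
EXCH_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
EXCH_NAMES = ("AC", "AG", "AT", "CG", "CT", "GT")
BRANCHES = ("human", "rhesus", "mouse")

# pattern code = h*16 + r*4 + m over unambiguous columns
_P64 = np.arange(64)
_H64, _R64, _M64 = _P64 // 16, (_P64 // 4) % 4, _P64 % 4


class PhyloError(ValueError):
    pass


@dataclass
class GTRModel:
    """A fitted (or specified) GTR model with branch lengths.

    ``exchangeabilities`` are the six symmetric rates in order
    AC, AG, AT, CG, CT, GT; the rate matrix is normalized so that the
    expected substitution rate at stationarity is 1 per unit branch length.
    """

    exchangeabilities: np.ndarray
    base_frequencies: np.ndarray
    branch_lengths: dict[str, float]
    log_l: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
        if self.exchangeabilities.shape != (6,) or (self.exchangeabilities < 0).any():
            raise PhyloError("exchangeabilities must be 6 nonnegative rates")
        if self.base_frequencies.shape != (4,) or abs(self.base_frequencies.sum() - 1) > 1e-12:
            raise PhyloError("base_frequencies must be 4 probabilities summing to 1")
        for b in BRANCHES:
            if b not in self.branch_lengths:
                raise PhyloError(f"missing branch length: {b}")
            if self.branch_lengths[b] < 0:
                raise PhyloError(f"negative branch length: {b}")

    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self.exchangeabilities, self.base_frequencies)

    def transition_matrices(self) -> dict[str, np.ndarray]:
        q = self.rate_matrix()
        return {
            b: transition_matrix(q, self.base_frequencies, self.branch_lengths[b])
            for b in BRANCHES
        }

    def to_yaml(self, path) -> None:
        payload = {
            "exchangeabilities": {n: float(v) for n, v in zip(EXCH_NAMES, self.exchangeabilities)},
            "base_frequencies": {b: float(v) for b, v in zip(BASES, self.base_frequencies)},
            "branch_lengths": {k: float(v) for k, v in self.branch_lengths.items()},
            "log_likelihood": None if self.log_l is None else float(self.log_l),
            "converged": bool(self.converged),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GTRModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            exchangeabilities=np.array([payload["exchangeabilities"][n] for n in EXCH_NAMES]),
            base_frequencies=np.array([payload["base_frequencies"][b] for b in BASES]),
            branch_lengths=dict(payload["branch_lengths"]),
            log_l=payload.get("log_likelihood"),
            converged=payload.get("converged", True),
        )


def build_rate_matrix(exch: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """GTR rate matrix Q_ij = s_ij * pi_j, normalized to one expected
    substitution per unit time at stationarity."""
    q = np.zeros((4, 4))
    for s, (i, j) in zip(exch, EXCH_PAIRS):
        q[i, j] = s * pi[j]
        q[j, i] = s * pi[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    if scale <= 0:
        raise PhyloError("degenerate rate matrix (zero total rate)")
    return q / scale


def transition_matrix(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """exp(Q t) via symmetric eigendecomposition of the pi^{1/2} similarity
    transform (stable for reversible Q)."""
    if t == 0:
        return np.eye(4)
    sq = np.sqrt(pi)
    a = (sq[:, None] * q) / sq[None, :]
    a = (a + a.T) / 2.0
    w, u = np.linalg.eigh(a)
    p = (u * np.exp(w * t)) @ u.T
    p = p / sq[:, None] * sq[None, :]
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=1, keepdims=True)


def pattern_counts(aln: TripletAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Collapse unambiguous columns to the 64 (human, rhesus, mouse) site
    patterns; returns (per-column pattern code with -1 at masked, counts)."""
    h, r, m = aln.codes()
    mask = (h < 4) & (r < 4) & (m < 4)
    codes = np.where(mask, h.astype(np.int32) * 16 + r * 4 + m, -1)
    counts = np.bincount(codes[mask], minlength=64)
    return codes, counts


def _pattern_joint(model: GTRModel) -> np.ndarray:
    """joint[a, p] = pi_a * P_h[a, h_p] * P_r[a, r_p] * P_m[a, m_p]."""
    pmats = model.transition_matrices()
    pi = model.base_frequencies
    return (
        pi[:, None]
        * pmats["human"][:, _H64]
        * pmats["rhesus"][:, _R64]
        * pmats["mouse"][:, _M64]
    )


def log_likelihood(aln: TripletAlignment, model: GTRModel) -> float:
    """Pruning log-likelihood over unambiguous columns."""
    _, counts = pattern_counts(aln)
    site_l = _pattern_joint(model).sum(axis=0)
    used = counts > 0
    if (site_l[used] <= 0).any():
        raise PhyloError("zero-probability site pattern (zero branch length with conflict?)")
    return float(counts[used] @ np.log(site_l[used]))


def _counts_loglik(counts: np.ndarray, exch, pi, t) -> float:
    model = GTRModel(exch, pi, dict(zip(BRANCHES, t)))
    site_l = _pattern_joint(model).sum(axis=0)
    used = counts > 0
    sl = np.maximum(site_l[used], 1e-300)
    return float(counts[used] @ np.log(sl))


def _eigendecompose(exch, pi):
    q = build_rate_matrix(np.asarray(exch, float), pi)
    sq = np.sqrt(pi)
    a = (sq[:, None] * q) / sq[None, :]
    a = (a + a.T) / 2.0
    w, u = np.linalg.eigh(a)
    left = u / sq[:, None]   # rows scaled: P(t) = diag(1/sq) U e^{wt} U^T diag(sq)
    right = (u * sq[:, None]).T
    return w, left, right


def _fast_loglik_factory(counts: np.ndarray, pi: np.ndarray):
    """Closure computing the pruning log-likelihood from raw parameter
    arrays, reusing the eigendecomposition across branch lengths and
    caching it per exchangeability vector."""
    used = np.flatnonzero(counts > 0)
    cnt = counts[used].astype(float)
    h, r, m = _H64[used], _R64[used], _M64[used]
    cache: dict[tuple, tuple] = {}

    def loglik(exch, t) -> float:
        key = tuple(np.round(exch, 12))
        eig = cache.get(key)
        if eig is None:
            if len(cache) > 8:
                cache.clear()
            eig = _eigendecompose(exch, pi)
            cache[key] = eig
        w, left, right = eig
        pmats = []
        for tb in t:
            p = (left * np.exp(w * tb)) @ right
            np.clip(p, 1e-300, None, out=p)
            pmats.append(p)
        site_l = (pi[:, None] * pmats[0][:, h] * pmats[1][:, r] * pmats[2][:, m]).sum(axis=0)
        return float(cnt @ np.log(np.maximum(site_l, 1e-300)))

    return loglik


def empirical_frequencies(aln: TripletAlignment) -> np.ndarray:
    """Observed base frequencies over all three sequences at unambiguous
    columns, with a half-count pseudofrequency to avoid zeros."""
    h, r, m = aln.codes()
    mask = (h < 4) & (r < 4) & (m < 4)
    counts = (
        np.bincount(h[mask], minlength=4)
        + np.bincount(r[mask], minlength=4)
        + np.bincount(m[mask], minlength=4)
    ).astype(float) + 0.5
    return counts / counts.sum()


def _init_branch_lengths(aln: TripletAlignment) -> np.ndarray:
    """Additive (three-point) initialization from JC-corrected pairwise
    mismatch fractions."""
    h, r, m = aln.codes()
    mask = (h < 4) & (r < 4) & (m < 4)
    n = max(int(mask.sum()), 1)

    def jc(x, y):
        p = min((x[mask] != y[mask]).sum() / n, 0.70)
        return -0.75 * np.log1p(-4.0 * p / 3.0) if p > 0 else 1e-6

    d_hr, d_hm, d_rm = jc(h, r), jc(h, m), jc(r, m)
    t = np.array(
        [
            (d_hr + d_hm - d_rm) / 2.0,
            (d_hr + d_rm - d_hm) / 2.0,
            (d_hm + d_rm - d_hr) / 2.0,
        ]
    )
    return np.clip(t, 1e-6, 8.0)


def fit_branch_lengths(
    aln: TripletAlignment,
    model: GTRModel | None = None,
    fit_exchangeabilities: bool = True,
    max_restarts: int = 2,
) -> GTRModel:
    """Maximum-likelihood branch lengths (and optionally exchangeabilities).

    Base frequencies are set to the observed frequencies.  Optimization is
    quasi-Newton (L-BFGS-B) in log-parameter space with branch-length
    bounds [1e-8, 10]; the GT exchangeability is fixed at 1 as the scale
    reference.  Non-convergence after restarts is flagged on the result,
    never silent.
    """
    _, counts = pattern_counts(aln)
    n_sites = int(counts.sum())
    if n_sites == 0:
        raise PhyloError(f"{aln.intron_id}: no unambiguous columns")
    if n_sites < 100:
        warnings.warn(
            f"{aln.intron_id}: only {n_sites} unambiguous columns; estimates will be noisy",
            stacklevel=2,
        )
    pi = model.base_frequencies if model is not None else empirical_frequencies(aln)
    if model is not None:
        exch0 = np.maximum(model.exchangeabilities, 1e-4)
    else:
        exch0 = np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0])
    t0 = _init_branch_lengths(aln)

    loglik = _fast_loglik_factory(counts, pi)

    def unpack(x):
        t = np.exp(x[:3])
        if fit_exchangeabilities:
            exch = np.empty(6)
            exch[:5] = np.exp(x[3:8])
            exch[5] = 1.0
        else:
            exch = exch0
        return exch, t

    def nll(x):
        exch, t = unpack(x)
        return -loglik(exch, t)

    if fit_exchangeabilities:
        x0 = np.concatenate([np.log(t0), np.log(exch0[:5] / exch0[5])])
        bounds = [(np.log(1e-8), np.log(10.0))] * 3 + [(np.log(1e-4), np.log(1e4))] * 5
    else:
        x0 = np.log(t0)
        bounds = [(np.log(1e-8), np.log(10.0))] * 3

    best = None
    starts = [x0]
    rng = np.random.default_rng(0)
    for _ in range(max_restarts - 1):
        starts.append(x0 + rng.normal(0, 0.5, size=x0.shape))
    for start in starts:
        res = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if best.success:
            break
    exch, t = unpack(best.x)
    return GTRModel(
        exchangeabilities=exch,
        base_frequencies=pi,
        branch_lengths=dict(zip(BRANCHES, (float(v) for v in t))),
        log_l=-float(best.fun),
        converged=bool(best.success),
    )


@dataclass
class AncestralProfile:
    """Marginal reconstruction of the human-rhesus ancestor.

    ``posterior`` has one row per alignment column (NaN at masked columns);
    ``map_codes`` is the argmax base (0..3; 4 at masked columns) with
    alphabetical tie-break A < C < G < T; ``mask`` flags usable columns.
    """

    posterior: np.ndarray
    map_codes: np.ndarray
    mask: np.ndarray

    @property
    def map_sequence(self) -> str:
        from cpgrates.alignments import codes_to_seq

        return codes_to_seq(self.map_codes)


def reconstruct_ancestor(aln: TripletAlignment, model: GTRModel) -> AncestralProfile:
    """Per-column posterior of the human-rhesus ancestor state given all
    three leaves (marginal reconstruction under the fitted model)."""
    codes, _ = pattern_counts(aln)
    joint = _pattern_joint(model)  # (4, 64)
    norm = joint.sum(axis=0)
    post64 = (joint / np.maximum(norm, 1e-300)).T  # (64, 4)
    map64 = post64.argmax(axis=1).astype(np.int8)

    n = len(codes)
    mask = codes >= 0
    posterior = np.full((n, 4), np.nan)
    posterior[mask] = post64[codes[mask]]
    map_codes = np.full(n, 4, dtype=np.int8)
    map_codes[mask] = map64[codes[mask]]
    return AncestralProfile(posterior=posterior, map_codes=map_codes, mask=mask)


def models_to_tsv(models: dict[str, GTRModel], path) -> None:
    """Per-intron fitted-model table."""
    import pandas as pd

    rows = []
    for intron_id, m in models.items():
        row = {"intron_id": intron_id}
        row.update({f"s_{n}": v for n, v in zip(EXCH_NAMES, m.exchangeabilities)})
        row.update({f"pi_{b}": v for b, v in zip(BASES, m.base_frequencies)})
        row.update({f"t_{b}": m.branch_lengths[b] for b in BRANCHES})
        row["log_likelihood"] = m.log_l
        row["converged"] = m.converged
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
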