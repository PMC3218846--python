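"""Strand-resolved dinucleotide substitution counting against the MAP
ancestor, and non-CpG divergence with triple-species CpG masking.

Events are oriented by parsimony: the reconstructed human-rhesus ancestor
defines the ancestral state, the human leaf the derived one.  A CpG
dinucleotide is self-complementary, so a C->T transition on the written
strand reads CpG -> TpG while the same chemistry on the opposite strand
reads CpG -> CpA; both are CpG transitions, attributed to the coding and
non-coding strand respectively (alignments are stored on the coding
strand of the host gene).  CpG transversions are CpG -> RpG or CpG -> CpY
(R in {A, G}, i.e. the C mutated on either strand).  CpH transitions are
CpH -> TpH on the written strand plus the opposite-strand counterpart
DpG -> DpA (H = not G, D = not C).  Site denominators always count the
ancestral sequence.  Dinucleotides in which both positions changed cannot
be oriented by parsimony; they are excluded from the event counts and
tallied separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from cpgrates.alignments import TripletAlignment, seq_to_codes
from cpgrates.phylo import AncestralProfile

A, C, G, T = 0, 1, 2, 3


class RatesError(ValueError):
    pass


@dataclass
class DinucRates:
    """Per-intron dinucleotide substitution counts and rates."""

    intron_id: str
    n_cpg_sites: int = 0
    n_cpg_ts: int = 0
    n_cpg_tv: int = 0
    n_cpg_ts_coding: int = 0
    n_cpg_ts_noncoding: int = 0
    n_cpg_double: int = 0
    n_cph_sites: int = 0
    n_cph_ts: int = 0
    noncpg_divergence: float = math.nan
    n_noncpg_sites: int = 0

    @property
    def cpg_ts_rate(self) -> float:
        return self.n_cpg_ts / self.n_cpg_sites if self.n_cpg_sites else math.nan

    @property
    def cpg_tv_rate(self) -> float:
        return self.n_cpg_tv / self.n_cpg_sites if self.n_cpg_sites else math.nan

    @property
    def cph_ts_rate(self) -> float:
        return self.n_cph_ts / self.n_cph_sites if self.n_cph_sites else math.nan

    @property
    def kappa(self) -> float:
        """CpG transition/transversion rate ratio; defined only when the
        transversion rate is positive."""
        if self.n_cpg_sites and self.n_cpg_tv > 0:
            return self.cpg_ts_rate / self.cpg_tv_rate
        return math.nan

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(
            cpg_ts_rate=self.cpg_ts_rate,
            cpg_tv_rate=self.cpg_tv_rate,
            cph_ts_rate=self.cph_ts_rate,
            kappa=self.kappa,
        )
        return d


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return seq_to_codes(seq)
    return np.asarray(seq, dtype=np.int8)


def scan_dinucleotide_events(
    ancestor, human, mask: np.ndarray | None = None, intron_id: str = ""
) -> DinucRates:
    """Count CpG/CpH events between the MAP ancestor and the human leaf.

    ``mask`` (optional) marks columns that are unusable (non-ACGT in any
    species); a dinucleotide is scanned only when both its positions are
    usable and unambiguous in both input sequences.
    """
    anc = _as_codes(ancestor)
    hum = _as_codes(human)
    if anc.size != hum.size:
        raise RatesError(f"length mismatch: ancestor {anc.size}, human {hum.size}")
    ok = (anc < 4) & (hum < 4)
    if mask is not None:
        ok &= np.asarray(mask, bool)
    pair_ok = ok[:-1] & ok[1:]
    a1, a2 = anc[:-1], anc[1:]
    h1, h2 = hum[:-1], hum[1:]

    res = DinucRates(intron_id=intron_id)

    anc_cpg = pair_ok & (a1 == C) & (a2 == G)
    res.n_cpg_sites = int(anc_cpg.sum())
    # single-position changes at ancestral CpG
    c_changed = anc_cpg & (h1 != C) & (h2 == G)
    g_changed = anc_cpg & (h1 == C) & (h2 != G)
    res.n_cpg_ts_coding = int((c_changed & (h1 == T)).sum())  # CpG -> TpG
    res.n_cpg_ts_noncoding = int((g_changed & (h2 == A)).sum())  # CpG -> CpA
    res.n_cpg_ts = res.n_cpg_ts_coding + res.n_cpg_ts_noncoding
    res.n_cpg_tv = int(
        (c_changed & ((h1 == A) | (h1 == G))).sum()  # CpG -> RpG
        + (g_changed & ((h2 == C) | (h2 == T))).sum()  # CpG -> CpC / CpT
    )
    res.n_cpg_double = int((anc_cpg & (h1 != C) & (h2 != G)).sum())

    # CpH on the written strand (H = A, C, T) and DpG on the opposite (D = A, G, T)
    anc_cph = pair_ok & (a1 == C) & (a2 != G)
    anc_dpg = pair_ok & (a1 != C) & (a2 == G)
    res.n_cph_sites = int(anc_cph.sum() + anc_dpg.sum())
    res.n_cph_ts = int(
        (anc_cph & (h1 == T) & (h2 == a2)).sum() + (anc_dpg & (h1 == a1) & (h2 == A)).sum()
    )
    return res


def noncpg_divergence(
    aln: TripletAlignment, profile: AncestralProfile, intron_id: str | None = None
) -> tuple[float, int]:
    """Human-branch divergence per site after masking both positions of
    every dinucleotide that is CpG in any of the three leaf sequences.

    Returns ``(divergence, n_sites)``; divergence is NaN when no usable
    site remains.
    """
    h, r, m = aln.codes()
    usable = profile.mask & (profile.map_codes < 4)
    cpg_mask = np.zeros(aln.length, dtype=bool)
    for s in (h, r, m):
        is_cg = (s[:-1] == C) & (s[1:] == G)
        cpg_mask[:-1] |= is_cg
        cpg_mask[1:] |= is_cg
    keep = usable & ~cpg_mask
    n = int(keep.sum())
    if n == 0:
        return math.nan, 0
    mismatches = int((profile.map_codes[keep] != h[keep]).sum())
    return mismatches / n, n


def counting_estimator(aln: TripletAlignment) -> float:
    """Outgroup-free CpG transition rate: sites that are CpG in rhesus and
    TpG or CpA in human, per rhesus CpG site (cross-check only)."""
    h, r, _ = aln.codes()
    ok = aln.column_mask()
    pair_ok = ok[:-1] & ok[1:]
    r_cpg = pair_ok & (r[:-1] == C) & (r[1:] == G)
    n_sites = int(r_cpg.sum())
    if n_sites == 0:
        return math.nan
    h1, h2 = h[:-1], h[1:]
    ts = r_cpg & (((h1 == T) & (h2 == G)) | ((h1 == C) & (h2 == A)))
    return int(ts.sum()) / n_sites


def strand_bias(rates_set: list[DinucRates] | pd.DataFrame, dataset_label: str = "") -> dict:
    """Empirical 95% percentile interval of the standardized coding vs
    non-coding CpG transition difference.

    Per intron, d = (n_coding - n_noncoding) / (n_coding + n_noncoding)
    over the shared ancestral-CpG denominator; introns with no event on
    either strand are excluded.  Returns the 2.5th-97.5th percentile
    interval of d and whether it covers zero.
    """
    if isinstance(rates_set, pd.DataFrame):
        nc = rates_set["n_cpg_ts_coding"].to_numpy(float)
        nn = rates_set["n_cpg_ts_noncoding"].to_numpy(float)
    else:
        nc = np.array([r.n_cpg_ts_coding for r in rates_set], float)
        nn = np.array([r.n_cpg_ts_noncoding for r in rates_set], float)
    tot = nc + nn
    use = tot > 0
    if use.sum() < 30:
        raise RatesError(f"strand_bias needs >= 30 introns with events, got {int(use.sum())}")
    d = (nc[use] - nn[use]) / tot[use]
    lo, hi = np.percentile(d, [2.5, 97.5])
    return {
        "dataset": dataset_label,
        "n": int(use.sum()),
        "low": float(lo),
        "high": float(hi),
        "covers_zero": bool(lo <= 0.0 <= hi),
        "mean_d": float(d.mean()),
    }


def rates_table(rates: list[DinucRates]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rates])
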