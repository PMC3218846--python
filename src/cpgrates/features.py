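"""Per-intron explanatory variables and dataset classification.

Covariates: CpG-count-weighted germ-line methylation over 100-bp windows,
GC content and CpG observed/expected ratio over unambiguous sites, mean
log expression index, log10(cM/Mb + 0.01) female/male recombination from
1-Mb windows, and the A/B/C dataset label from CGI/DHS overlap.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from cpgrates.alignments import GenomicTrack, TripletAlignment, seq_to_codes

A, C, G, T = 0, 1, 2, 3


class FeatureError(ValueError):
    pass


def _codes(seq) -> np.ndarray:
    return seq_to_codes(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int8)


def gc_content(seq) -> float:
    """(#G + #C) / #ACGT over unambiguous positions; NaN when none."""
    codes = _codes(seq)
    ok = codes < 4
    n = int(ok.sum())
    if n == 0:
        return math.nan
    gc = int(((codes == C) | (codes == G)).sum())
    return gc / n


def cpg_oe(seq) -> float:
    """Observed/expected CpG: p(CpG) / (p(C) * p(G)).

    p(C), p(G) are frequencies over unambiguous bases; p(CpG) is the count
    of CpG dinucleotides (both positions unambiguous) over the number of
    unambiguous overlapping dinucleotide positions.  Missing (NaN) when
    p(C) or p(G) is zero.
    """
    codes = _codes(seq)
    ok = codes < 4
    n = int(ok.sum())
    if n == 0:
        return math.nan
    pc = int((codes == C).sum()) / n
    pg = int((codes == G).sum()) / n
    if pc == 0.0 or pg == 0.0:
        return math.nan
    pair_ok = ok[:-1] & ok[1:]
    n_pairs = int(pair_ok.sum())
    if n_pairs == 0:
        return math.nan
    n_cpg = int((pair_ok & (codes[:-1] == C) & (codes[1:] == G)).sum())
    return (n_cpg / n_pairs) / (pc * pg)


def methylation_level(
    intron: TripletAlignment | tuple, track: GenomicTrack, min_windows: int = 5
) -> tuple[float, int]:
    """CpG-count-weighted mean methylation over 100-bp windows fully
    contained in the intron.

    Returns ``(level, n_windows)``; level is NaN when fewer than
    ``min_windows`` windows are available or the total CpG weight is zero.
    """
    chrom, start, end = (
        (intron.chrom, intron.start, intron.end) if isinstance(intron, TripletAlignment) else intron
    )
    sub = track.overlap_query(chrom, start, end, mode="contained")
    n = len(sub)
    if n < min_windows:
        return math.nan, n
    w = sub["cpg_count"].to_numpy(float)
    m = sub["methylation"].to_numpy(float)
    if w.sum() <= 0:
        return math.nan, n
    return float((m * w).sum() / w.sum()), n


def expression_level(indices, log_base: str = "natural") -> float:
    """Mean of log-transformed replicate expression indices."""
    x = np.asarray(indices, float)
    if (x <= 0).any():
        raise FeatureError(f"nonpositive expression index: {x.min()}")
    logs = np.log(x) if log_base == "natural" else np.log10(x)
    return float(logs.mean())


def recombination_features(
    intron: TripletAlignment | tuple, track: GenomicTrack
) -> tuple[float, float]:
    """log10(rate + 0.01) for each sex from the 1-Mb window containing the
    intron midpoint; NaN when no window covers it."""
    chrom, start, end = (
        (intron.chrom, intron.start, intron.end) if isinstance(intron, TripletAlignment) else intron
    )
    mid = (start + end) // 2
    hit = track.overlap_query(chrom, mid, mid + 1, mode="any")
    if len(hit) == 0:
        return math.nan, math.nan
    row = hit.iloc[0]
    return (
        float(np.log10(row["female"] + 0.01)),
        float(np.log10(row["male"] + 0.01)),
    )


def detect_cgi(
    seq,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    window: int = 200,
) -> list[tuple[int, int]]:
    """CpG-island detection under the Gardiner-Garden criteria.

    Slides a ``window``-bp window with step 1 over the sequence; windows
    with GC >= ``min_gc`` and CpG o/e >= ``min_oe`` are merged when they
    overlap, and each merged region is re-checked against both thresholds
    (regions failing the re-check, or shorter than ``min_length``, are
    dropped).  Returns intron-local half-open intervals.
    """
    codes = _codes(seq)
    L = codes.size
    if L < window:
        return []
    is_c = (codes == C).astype(np.int64)
    is_g = (codes == G).astype(np.int64)
    is_ok = (codes < 4).astype(np.int64)
    is_cg = np.zeros(L, np.int64)
    is_cg[:-1] = (codes[:-1] == C) & (codes[1:] == G)

    def csum(x):
        out = np.zeros(L + 1, np.int64)
        np.cumsum(x, out=out[1:])
        return out

    cs_c, cs_g, cs_ok, cs_cg = csum(is_c), csum(is_g), csum(is_ok), csum(is_cg)

    starts = np.arange(0, L - window + 1)
    ends = starts + window
    n_ok = cs_ok[ends] - cs_ok[starts]
    n_c = cs_c[ends] - cs_c[starts]
    n_g = cs_g[ends] - cs_g[starts]
    n_cg = cs_cg[ends - 1] - cs_cg[starts]  # pairs fully inside the window
    n_pairs = np.maximum(n_ok - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(n_ok > 0, (n_c + n_g) / np.maximum(n_ok, 1), 0.0)
        pc = n_c / np.maximum(n_ok, 1)
        pg = n_g / np.maximum(n_ok, 1)
        oe = np.where((pc > 0) & (pg > 0), (n_cg / n_pairs) / np.maximum(pc * pg, 1e-300), 0.0)
    qual = (gc >= min_gc) & (oe >= min_oe) & (n_ok == window)

    regions: list[tuple[int, int]] = []
    i = 0
    nq = qual.size
    while i < nq:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < nq and qual[j + 1]:
            j += 1
        regions.append((int(starts[i]), int(ends[j])))
        i = j + 1

    out = []
    for s, e in regions:
        if e - s < min_length:
            continue
        sub = codes[s:e]
        if gc_content(sub) >= min_gc and cpg_oe(sub) >= min_oe:
            out.append((s, e))
    return out


def detect_cgi_track(
    alignments: list[TripletAlignment],
    min_length: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    window: int = 200,
) -> GenomicTrack:
    """Sequence-based CGI annotation: run the Gardiner-Garden detector on
    each intron's ungapped human sequence and report genomic intervals.

    Used when no CGI interval track is supplied (CGIs are sequence-defined;
    DHS annotations, by contrast, are always consumed as given).
    """
    rows = []
    for aln in alignments:
        ungapped = aln.seq_human.replace("-", "")
        for s, e in detect_cgi(ungapped, min_length=min_length, min_gc=min_gc,
                               min_oe=min_oe, window=window):
            rows.append((aln.chrom, aln.start + s, aln.start + e))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if len(df):
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    else:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=int),
                           "end": pd.Series(dtype=int)})
    return GenomicTrack(df, name="cgi-detected")


def classify_intron(has_cgi: bool, has_dhs: bool) -> str:
    """Dataset label: A = neither, B = DHS only, C = both, discard = CGI only."""
    if has_cgi:
        return "C" if has_dhs else "discard"
    return "B" if has_dhs else "A"


def build_features(
    alignments: list[TripletAlignment],
    methylation_track: GenomicTrack,
    recombination_track: GenomicTrack,
    cgi_track: GenomicTrack | None,
    dhs_track: GenomicTrack | None,
    expression: pd.DataFrame,
    min_meth_windows: int = 5,
    log_base: str = "natural",
) -> pd.DataFrame:
    """Join all per-intron explanatory variables into one table.

    CGI/DHS flags come from any-overlap queries against the annotation
    tracks (intervals consumed as given).  Expression rows need columns
    gene_id, index_1..index_3.
    """
    expr_map = {}
    rep_cols = [c for c in expression.columns if c.startswith("index")]
    for row in expression.itertuples(index=False):
        expr_map[row.gene_id] = expression_level(
            [getattr(row, c) for c in rep_cols], log_base=log_base
        )
    rows = []
    for aln in alignments:
        meth, n_win = methylation_level(aln, methylation_track, min_windows=min_meth_windows)
        recf, recm = recombination_features(aln, recombination_track)
        has_cgi = (
            len(cgi_track.overlap_query(aln.chrom, aln.start, aln.end, mode="any")) > 0
            if cgi_track is not None
            else False
        )
        has_dhs = (
            len(dhs_track.overlap_query(aln.chrom, aln.start, aln.end, mode="any")) > 0
            if dhs_track is not None
            else False
        )
        rows.append(
            {
                "intron_id": aln.intron_id,
                "gene_id": aln.gene_id,
                "chrom": aln.chrom,
                "methylation": meth,
                "n_meth_windows": n_win,
                "gc_content": gc_content(aln.seq_human),
                "cpg_oe": cpg_oe(aln.seq_human),
                "expression": expr_map.get(aln.gene_id, math.nan),
                "recomb_female": recf,
                "recomb_male": recm,
                "has_cgi": has_cgi,
                "has_dhs": has_dhs,
                "dataset": classify_intron(has_cgi, has_dhs),
            }
        )
    return pd.DataFrame(rows)
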