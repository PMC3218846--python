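"""Synthetic study generator: context-dependent sequence evolution with
methylation-modulated CpG hypermutability, plus consistent feature tracks.

The generator evolves gap-free triplet alignments on the
((human, rhesus), mouse) topology.  Each intron carries a true germ-line
methylation level m; the CpG transition multiplier is linear in m,
lambda(m) = 1 + (lambda_max - 1) * m, applied to C->T (and, strand
symmetrically, G->A) in CpG context only.  CpG transversions get a
constant context multiplier, so the CpG transition/transversion ratio
grows with methylation.  A per-intron log-normal rate scalar models
regional mutation-rate variation (the driver of non-CpG divergence), and
may additionally be tilted by GC content, expression and recombination.
X-linked introns have all branches shortened by the standard male-bias
factor X/A = 2(2 + alpha) / (3 (1 + alpha)).

Emitted artifacts mirror the study's inputs: FASTA triplet alignments,
100-bp methylation windows with per-window CpG counts (BED-like), a
three-replicate expression table, 1-Mb female/male recombination windows,
CGI/DHS interval BEDs consistent with the A/B/C dataset labels, and a
ground-truth table with complete per-branch event logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from cpgrates import _gillespie
from cpgrates.alignments import GenomicTrack, TripletAlignment, codes_to_seq, write_alignments
from cpgrates.phylo import build_rate_matrix

DATASET_CLASSES = ("A", "B", "C", "discard")


class ConfigError(ValueError):
    pass


# Default methylation mixtures: classes A and B high and narrow, class C
# broad/bimodal (low-methylation CGI-like component plus a methylated one).
_DEFAULT_METHYLATION = {
    "A": [{"weight": 1.0, "a": 10.9, "b": 3.2}],
    "B": [{"weight": 1.0, "a": 8.8, "b": 2.8}],
    "C": [{"weight": 0.5, "a": 2.5, "b": 7.5}, {"weight": 0.5, "a": 7.0, "b": 3.0}],
}
# Equilibrium GC targets per class (Beta distributions around ~0.40-0.47).
_DEFAULT_GC = {
    "A": {"a": 28.5, "b": 43.4},
    "B": {"a": 25.8, "b": 35.3},
    "C": {"a": 21.2, "b": 23.8},
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Branch lengths are expected substitutions/site at non-CpG sites.
    ``cpg_ts_multiplier_max`` is lambda_max in
    lambda(m) = 1 + (lambda_max - 1) m.
    """

    n_introns: int = 200
    intron_length: int = 1500
    branch_lengths: dict = field(
        default_factory=lambda: {"human": 0.02, "rhesus": 0.025, "mouse": 0.35}
    )
    gtr_exchangeabilities: tuple = (1.0, 4.0, 1.0, 1.0, 4.0, 1.0)
    base_frequencies: tuple = (0.3, 0.2, 0.2, 0.3)
    cpg_ts_multiplier_max: float = 12.0
    cpg_tv_multiplier: float = 2.0
    strand_symmetric: bool = True
    methylation_distribution: dict = field(default_factory=lambda: dict(_DEFAULT_METHYLATION))
    gc_target_distribution: dict = field(default_factory=lambda: dict(_DEFAULT_GC))
    dataset_weights: dict = field(
        default_factory=lambda: {"A": 0.337, "B": 0.560, "C": 0.100, "discard": 0.003}
    )
    rate_heterogeneity_sigma: float = 0.3
    gc_effect: float = -2.0
    expression_effect: float = 0.0
    recombination_effect: float = 0.0
    expression_mean: float = 2.59
    expression_sd: float = 0.64
    expression_replicate_sd: float = 0.2
    recomb_female_log10_mean: float = 0.072
    recomb_female_log10_sd: float = 0.45
    recomb_male_log10_mean: float = -0.397
    recomb_male_log10_sd: float = 0.71
    male_bias_alpha: float = 1.0
    x_fraction: float = 0.0
    autosomes: tuple = ("chr1", "chr2", "chr3", "chr4", "chr5", "chr6")
    introns_per_gene_mean: float = 3.0
    burn_in_time: float = 3.0
    meth_window_noise_sd: float = 0.05
    meth_window_missing: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_introns < 1 or self.intron_length < 2:
            raise ConfigError("n_introns >= 1 and intron_length >= 2 required")
        pi = np.asarray(self.base_frequencies, float)
        if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-12 or (pi <= 0).any():
            raise ConfigError("base_frequencies must be 4 positive probabilities summing to 1")
        if self.cpg_ts_multiplier_max < 1.0:
            raise ConfigError("cpg_ts_multiplier_max (lambda_max) must be >= 1")
        if self.cpg_tv_multiplier < 0.0:
            raise ConfigError("cpg_tv_multiplier must be >= 0")
        if any(v <= 0 for v in self.branch_lengths.values()):
            raise ConfigError("branch lengths must be > 0")
        if len(np.asarray(self.gtr_exchangeabilities)) != 6 or any(
            v < 0 for v in self.gtr_exchangeabilities
        ):
            raise ConfigError("gtr_exchangeabilities must be 6 nonnegative rates")
        w = self.dataset_weights
        if any(k not in DATASET_CLASSES for k in w):
            raise ConfigError(f"unknown dataset class in weights: {sorted(w)}")
        wv = np.array(list(w.values()), float)
        if (wv < 0).any() or wv.sum() <= 0:
            raise ConfigError("dataset_weights must be nonnegative with positive sum")
        for cls, mix in self.methylation_distribution.items():
            tot = sum(c.get("weight", 1.0) for c in mix)
            if any(c.get("weight", 1.0) < 0 for c in mix) or tot <= 0:
                raise ConfigError(f"invalid methylation mixture weights for class {cls!r}")
        if not 0 <= self.x_fraction <= 1:
            raise ConfigError("x_fraction must be in [0, 1]")
        if self.male_bias_alpha <= 0:
            raise ConfigError("male_bias_alpha must be > 0")

    def x_branch_scale(self) -> float:
        a = self.male_bias_alpha
        return 2.0 * (2.0 + a) / (3.0 * (1.0 + a))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**payload)


def pi_from_gc(gc: float) -> np.ndarray:
    """Strand-symmetric stationary frequencies with C + G = gc."""
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _offdiag_rates(exch, pi) -> np.ndarray:
    q = build_rate_matrix(np.asarray(exch, float), np.asarray(pi, float))
    q = q.copy()
    np.fill_diagonal(q, 0.0)
    return q


def lambda_of_methylation(m: float, lam_max: float) -> float:
    return 1.0 + (lam_max - 1.0) * m


def _sample_mixture(mix: list[dict], n: int, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([c.get("weight", 1.0) for c in mix], float)
    weights = weights / weights.sum()
    comp = rng.choice(len(mix), size=n, p=weights)
    out = np.empty(n)
    for k, c in enumerate(mix):
        idx = comp == k
        if not idx.any():
            continue
        if "value" in c:
            out[idx] = c["value"]
        else:
            out[idx] = rng.beta(c["a"], c["b"], size=int(idx.sum()))
    return out


def _sample_dist(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    if "value" in spec:
        return np.full(n, float(spec["value"]))
    return rng.beta(spec["a"], spec["b"], size=n)


def draw_intron_parameters(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-intron ground-truth parameter table.

    Introns are grouped into genes, genes are placed on chromosomes
    (``chrX`` with probability ``x_fraction``), and each intron receives a
    dataset class, methylation level, equilibrium GC target, rate scalar,
    expression level and the recombination values of its 1-Mb window.  The
    1-Mb window track is attached as ``df.attrs["recomb_windows"]``.
    """
    n = config.n_introns
    classes = np.array(list(config.dataset_weights))
    wv = np.array(list(config.dataset_weights.values()), float)
    cls = rng.choice(classes, size=n, p=wv / wv.sum())

    # genes: 1 + Poisson-distributed extra introns, truncated to cover n
    sizes: list[int] = []
    covered = 0
    lam = max(config.introns_per_gene_mean - 1.0, 0.0)
    while covered < n:
        s = 1 + int(rng.poisson(lam))
        s = min(s, n - covered)
        sizes.append(s)
        covered += s
    n_genes = len(sizes)
    gene_ids = [f"G{g:05d}" for g in range(n_genes)]
    chrom_pool = list(config.autosomes)
    gene_chrom = [
        "chrX" if rng.random() < config.x_fraction else chrom_pool[int(rng.integers(len(chrom_pool)))]
        for _ in range(n_genes)
    ]
    expr_true = rng.normal(config.expression_mean, config.expression_sd, size=n_genes)

    intron_gene = np.repeat(np.arange(n_genes), sizes)

    methylation = np.empty(n)
    gc_target = np.empty(n)
    for c in np.unique(cls):
        key = "C" if c == "discard" else c
        idx = cls == c
        mix = config.methylation_distribution.get(key)
        if mix is None:
            raise ConfigError(f"no methylation distribution for class {key!r}")
        methylation[idx] = _sample_mixture(mix, int(idx.sum()), rng)
        gc_target[idx] = _sample_dist(config.gc_target_distribution[key], int(idx.sum()), rng)
    gc_target = np.clip(gc_target, 0.05, 0.95)

    # genomic placement: per chromosome, sequential with 200-bp gaps
    start = np.empty(n, dtype=np.int64)
    chrom = np.array([gene_chrom[g] for g in intron_gene])
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        cursor = 1000
        for i in idx:
            start[i] = cursor
            cursor += config.intron_length + 200
    end = start + config.intron_length

    # 1-Mb recombination windows covering every chromosome
    win_rows = []
    for c in np.unique(chrom):
        max_end = int(end[chrom == c].max())
        for ws in range(0, max_end + 1_000_000, 1_000_000):
            f = max(10 ** rng.normal(config.recomb_female_log10_mean, config.recomb_female_log10_sd) - 0.01, 0.0)
            m = max(10 ** rng.normal(config.recomb_male_log10_mean, config.recomb_male_log10_sd) - 0.01, 0.0)
            win_rows.append((c, ws, ws + 1_000_000, f, m))
    windows = pd.DataFrame(win_rows, columns=["chrom", "start", "end", "female", "male"])
    windows = windows.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    mid = (start + end) // 2
    win_f = np.empty(n)
    win_m = np.empty(n)
    for c, sub in windows.groupby("chrom"):
        idx = np.flatnonzero(chrom == c)
        pos = np.searchsorted(sub["start"].to_numpy(), mid[idx], side="right") - 1
        win_f[idx] = sub["female"].to_numpy()[pos]
        win_m[idx] = sub["male"].to_numpy()[pos]

    expression = expr_true[intron_gene]
    log_scalar = rng.normal(
        -config.rate_heterogeneity_sigma**2 / 2.0, config.rate_heterogeneity_sigma, size=n
    )
    log_scalar += config.gc_effect * (gc_target - gc_target.mean())
    log_scalar += config.expression_effect * (expression - expression.mean())
    recf_log = np.log10(win_f + 0.01)
    log_scalar += config.recombination_effect * (recf_log - recf_log.mean())
    rate_scalar = np.exp(log_scalar)

    branch_scale = np.where(chrom == "chrX", config.x_branch_scale(), 1.0)

    df = pd.DataFrame(
        {
            "intron_id": [f"I{i:05d}" for i in range(n)],
            "gene_id": [gene_ids[g] for g in intron_gene],
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": "+",
            "dataset_true": cls,
            "methylation_true": methylation,
            "gc_target": gc_target,
            "rate_scalar": rate_scalar,
            "branch_scale": branch_scale,
            "expression_true": expression,
            "recomb_female_true": win_f,
            "recomb_male_true": win_m,
        }
    )
    df.attrs["recomb_windows"] = windows
    return df


def cpg_oe_of_codes(codes: np.ndarray) -> float:
    """Observed/expected CpG of a plain coded sequence (no ambiguity)."""
    n = codes.size
    if n < 2:
        return math.nan
    pc = (codes == 1).mean()
    pg = (codes == 2).mean()
    if pc == 0 or pg == 0:
        return math.nan
    pcg = ((codes[:-1] == 1) & (codes[1:] == 2)).sum() / (n - 1)
    return pcg / (pc * pg)


def _run_kernel(seq, q, lam_ts, lam_tv, sym, t_max, rng, record):
    """Drive the Gillespie kernel, growing event buffers on demand."""
    if record:
        approx = expected_total_rate(seq, q, lam_ts, lam_tv, sym) * t_max
        cap = int(approx * 1.5 + 6.0 * math.sqrt(approx + 1.0) + 64)
    else:
        cap = 0
    site = np.empty(cap, dtype=np.int32)
    time = np.empty(cap, dtype=np.float64)
    frm = np.empty(cap, dtype=np.int8)
    to = np.empty(cap, dtype=np.int8)
    ctx = np.empty(cap, dtype=np.int8)
    chunks = []
    t0 = 0.0
    total = 0
    while True:
        seed = int(rng.integers(1, 2**31 - 1))
        nev, t_reached, full = _gillespie.gillespie_kernel(
            seq, q, lam_ts, lam_tv, sym, t0, t_max, seed, site, time, frm, to, ctx
        )
        total += nev
        if record and nev:
            chunks.append(
                (site[:nev].copy(), time[:nev].copy(), frm[:nev].copy(), to[:nev].copy(), ctx[:nev].copy())
            )
        if not full:
            break
        t0 = t_reached
        cap = max(2 * cap, 256)
        site = np.empty(cap, dtype=np.int32)
        time = np.empty(cap, dtype=np.float64)
        frm = np.empty(cap, dtype=np.int8)
        to = np.empty(cap, dtype=np.int8)
        ctx = np.empty(cap, dtype=np.int8)
    if not record:
        return total, None
    if chunks:
        events = pd.DataFrame(
            {
                "site": np.concatenate([c[0] for c in chunks]),
                "time": np.concatenate([c[1] for c in chunks]),
                "from_base": np.concatenate([c[2] for c in chunks]),
                "to_base": np.concatenate([c[3] for c in chunks]),
                "context": np.concatenate([c[4] for c in chunks]),
            }
        )
    else:
        events = pd.DataFrame(
            {
                "site": np.array([], dtype=np.int32),
                "time": np.array([], dtype=float),
                "from_base": np.array([], dtype=np.int8),
                "to_base": np.array([], dtype=np.int8),
                "context": np.array([], dtype=np.int8),
            }
        )
    return total, events


def expected_total_rate(
    codes: np.ndarray, q: np.ndarray, lam_ts: float, lam_tv: float, sym: bool = True
) -> float:
    """Total leaving rate of the current sequence state (vectorized)."""
    L = codes.size
    base = q[codes].sum(axis=1)
    is_cpg_c = np.zeros(L, bool)
    is_cpg_c[:-1] = (codes[:-1] == 1) & (codes[1:] == 2)
    extra = is_cpg_c * (q[1, 3] * (lam_ts - 1.0) + (q[1, 0] + q[1, 2]) * (lam_tv - 1.0))
    if sym:
        is_cpg_g = np.zeros(L, bool)
        is_cpg_g[1:] = (codes[:-1] == 1) & (codes[1:] == 2)
        extra = extra + is_cpg_g * (
            q[2, 0] * (lam_ts - 1.0) + (q[2, 3] + q[2, 1]) * (lam_tv - 1.0)
        )
    return float(base.sum() + extra.sum())


def equilibrium_root_sequence(
    gc_target: float,
    methylation: float,
    length: int,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
) -> np.ndarray:
    """Root sequence at context equilibrium, as int8 codes.

    Starts from an i.i.d. draw at the single-site stationary frequencies
    and burns in the context-dependent process until CpG o/e is stable:
    after the initial burn-in, further 10%-length extensions must change
    CpG o/e by less than 2% (plus a sampling-noise floor of three binomial
    standard errors of the CpG count, which matters for short sequences).
    """
    if length < 2:
        raise ConfigError("length must be >= 2")
    cfg = config or SimulationConfig(n_introns=1, intron_length=max(length, 2))
    pi = pi_from_gc(gc_target)
    q = _offdiag_rates(cfg.gtr_exchangeabilities, pi)
    lam_ts = lambda_of_methylation(methylation, cfg.cpg_ts_multiplier_max)
    lam_tv = cfg.cpg_tv_multiplier
    seq = rng.choice(4, size=length, p=pi).astype(np.int8)
    t_burn = cfg.burn_in_time
    _run_kernel(seq, q, lam_ts, lam_tv, cfg.strand_symmetric, t_burn, rng, record=False)
    prev_oe = cpg_oe_of_codes(seq)
    for _ in range(30):
        extra = 0.1 * t_burn
        _run_kernel(seq, q, lam_ts, lam_tv, cfg.strand_symmetric, extra, rng, record=False)
        t_burn += extra
        oe = cpg_oe_of_codes(seq)
        n_cpg = max(((seq[:-1] == 1) & (seq[1:] == 2)).sum(), 1)
        noise_floor = 3.0 * oe / math.sqrt(n_cpg) if np.isfinite(oe) else math.inf
        if not np.isfinite(oe) or not np.isfinite(prev_oe):
            break
        if abs(oe - prev_oe) < max(0.02 * prev_oe, noise_floor):
            break
        prev_oe = oe
    return seq


def evolve_branch(
    sequence: np.ndarray | str,
    branch_length: float,
    params: dict,
    rng: np.random.Generator,
    record: bool = True,
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Evolve one branch; returns the new sequence and the event log.

    ``params`` carries ``gc_target``, ``methylation`` and optionally
    ``exchangeabilities``, ``cpg_ts_multiplier_max``, ``cpg_tv_multiplier``,
    ``strand_symmetric``.  ``branch_length`` is in expected
    substitutions/site at non-CpG sites (already including any per-intron
    rate scalar).  Event-log columns: site, time, from_base, to_base,
    context (0 none, 1 CpG-C, 2 CpG-G).
    """
    if branch_length < 0:
        raise ConfigError("branch_length must be >= 0")
    if isinstance(sequence, str):
        from cpgrates.alignments import seq_to_codes

        seq = seq_to_codes(sequence).copy()
        if (seq > 3).any():
            raise ConfigError("sequence must be over {A,C,G,T}")
    else:
        seq = np.asarray(sequence, dtype=np.int8).copy()
    empty = pd.DataFrame(
        {
            "site": np.array([], dtype=np.int32),
            "time": np.array([], dtype=float),
            "from_base": np.array([], dtype=np.int8),
            "to_base": np.array([], dtype=np.int8),
            "context": np.array([], dtype=np.int8),
        }
    )
    if branch_length == 0:
        return seq, (empty if record else None)
    pi = pi_from_gc(params["gc_target"])
    exch = params.get("exchangeabilities", (1.0, 4.0, 1.0, 1.0, 4.0, 1.0))
    q = _offdiag_rates(exch, pi)
    lam_ts = lambda_of_methylation(
        params["methylation"], params.get("cpg_ts_multiplier_max", 12.0)
    )
    lam_tv = params.get("cpg_tv_multiplier", 2.0)
    sym = bool(params.get("strand_symmetric", True))
    _, events = _run_kernel(seq, q, lam_ts, lam_tv, sym, branch_length, rng, record=record)
    return seq, (events if record else None)


def replay_events(root: np.ndarray, events: pd.DataFrame) -> np.ndarray:
    """Re-apply an event log to the root sequence (consistency oracle)."""
    seq = np.asarray(root, dtype=np.int8).copy()
    order = np.argsort(events["time"].to_numpy(), kind="stable")
    sites = events["site"].to_numpy()[order]
    frm = events["from_base"].to_numpy()[order]
    to = events["to_base"].to_numpy()[order]
    for s, f, t in zip(sites, frm, to):
        if seq[s] != f:
            raise ValueError(f"event log inconsistent at site {s}: state {seq[s]}, logged from {f}")
        seq[s] = t
    return seq


@dataclass
class StudyBundle:
    """In-memory synthetic study: alignments, truth table, feature tracks."""

    config: SimulationConfig
    alignments: list[TripletAlignment]
    truth: pd.DataFrame
    methylation_track: GenomicTrack
    recombination_track: GenomicTrack
    cgi_track: GenomicTrack
    dhs_track: GenomicTrack
    expression: pd.DataFrame
    events: dict[str, dict[str, pd.DataFrame]]
    root_sequences: dict[str, np.ndarray]


def simulate_study(config: SimulationConfig, rng: np.random.Generator | None = None) -> StudyBundle:
    """Generate a full synthetic study under ``config``."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    params = draw_intron_parameters(config, rng)
    windows = params.attrs["recomb_windows"]

    exch = config.gtr_exchangeabilities
    alignments: list[TripletAlignment] = []
    events: dict[str, dict[str, pd.DataFrame]] = {}
    roots: dict[str, np.ndarray] = {}
    meth_rows = []
    cgi_rows = []
    dhs_rows = []

    for row in params.itertuples(index=False):
        lam_ts = lambda_of_methylation(row.methylation_true, config.cpg_ts_multiplier_max)
        lam_tv = config.cpg_tv_multiplier
        pi = pi_from_gc(row.gc_target)
        q = _offdiag_rates(exch, pi)
        root = equilibrium_root_sequence(
            row.gc_target, row.methylation_true, config.intron_length, rng, config
        )
        scale = row.rate_scalar * row.branch_scale
        leaf = {}
        ev = {}
        for branch in ("human", "rhesus", "mouse"):
            seq = root.copy()
            t = config.branch_lengths[branch] * scale
            _, branch_events = _run_kernel(
                seq, q, lam_ts, lam_tv, config.strand_symmetric, t, rng, record=True
            )
            leaf[branch] = seq
            ev[branch] = branch_events
        aln = TripletAlignment(
            intron_id=row.intron_id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            seq_human=codes_to_seq(leaf["human"]),
            seq_rhesus=codes_to_seq(leaf["rhesus"]),
            seq_mouse=codes_to_seq(leaf["mouse"]),
            gene_id=row.gene_id,
        )
        alignments.append(aln)
        events[row.intron_id] = ev
        roots[row.intron_id] = root

        # 100-bp methylation windows (grid-aligned, fully inside the intron)
        human = leaf["human"]
        w0 = ((row.start + 99) // 100) * 100
        w = w0
        while w + 100 <= row.end:
            if rng.random() >= config.meth_window_missing:
                off = w - row.start
                win = human[off : off + 100]
                n_cpg = int(((win[:-1] == 1) & (win[1:] == 2)).sum())
                m = float(
                    np.clip(row.methylation_true + rng.normal(0, config.meth_window_noise_sd), 0, 1)
                )
                meth_rows.append((row.chrom, w, w + 100, m, n_cpg))
            w += 100

        # CGI/DHS annotations consistent with the class label
        mid = (row.start + row.end) // 2
        if row.dataset_true in ("C", "discard"):
            cgi_rows.append((row.chrom, mid - 150, mid + 150))
        if row.dataset_true in ("B", "C"):
            dhs_rows.append((row.chrom, mid - 100, mid + 100))

    meth = pd.DataFrame(meth_rows, columns=["chrom", "start", "end", "methylation", "cpg_count"])
    meth = meth.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    def _bed(rows, name):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        return GenomicTrack(df, name=name) if len(df) else GenomicTrack(
            pd.DataFrame({"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=int),
                          "end": pd.Series(dtype=int)}), name=name)

    gene_expr = params.drop_duplicates("gene_id")[["gene_id", "expression_true"]]
    reps = {
        f"index_{k+1}": np.exp(
            gene_expr["expression_true"].to_numpy()
            + rng.normal(0, config.expression_replicate_sd, size=len(gene_expr))
        )
        for k in range(3)
    }
    expression = pd.DataFrame({"gene_id": gene_expr["gene_id"].to_numpy(), **reps})

    return StudyBundle(
        config=config,
        alignments=alignments,
        truth=params,
        methylation_track=GenomicTrack(meth, name="methylation"),
        recombination_track=GenomicTrack(windows, name="recombination"),
        cgi_track=_bed(cgi_rows, "cgi"),
        dhs_track=_bed(dhs_rows, "dhs"),
        expression=expression,
        events=events,
        root_sequences=roots,
    )


def emit_study_bundle(config: SimulationConfig, outdir, write_event_logs: bool = False) -> Path:
    """Write a synthetic study to ``outdir`` as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_study(config)
    write_alignments(bundle.alignments, out / "alignments.fasta", format="fasta-triplet")
    bundle.methylation_track.write_bed(out / "methylation.bed")
    bundle.recombination_track.write_bed(out / "recombination.bed")
    bundle.cgi_track.write_bed(out / "cgi.bed")
    bundle.dhs_track.write_bed(out / "dhs.bed")
    bundle.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    bundle.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {k: _yamlify(getattr(bundle.config, k)) for k in config.__dataclass_fields__}, fh
        )
    if write_event_logs:
        frames = []
        for intron_id, branches in bundle.events.items():
            for branch, ev in branches.items():
                e = ev.copy()
                e.insert(0, "branch", branch)
                e.insert(0, "intron_id", intron_id)
                frames.append(e)
        pd.concat(frames, ignore_index=True).to_csv(out / "events.tsv", sep="\t", index=False)
    return out


def _yamlify(v: Any):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, np.generic):
        return v.item()
    return v
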