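"""Three-taxon intron alignments and genomic interval tracks.

Coordinates are 0-based half-open throughout (BED convention).  Alignments
are stored on the coding strand of the host gene; an "unambiguous" column is
one where human, rhesus and mouse all carry a plain A/C/G/T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
#: base -> code; 0..3 = A,C,G,T; 4 = ambiguous (N, gap, anything else)
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

ALLOWED_CHARS = set("ACGTN-acgtn")


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes (A,C,G,T = 0..3; anything else = 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


class AlignmentError(ValueError):
    """Malformed alignment record."""


@dataclass
class TripletAlignment:
    """One intron's aligned human/rhesus/mouse sequences.

    ``start``/``end`` are human-assembly coordinates of the ungapped human
    sequence; ``strand`` is the coding strand of the host gene.
    """

    intron_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seq_human: str
    seq_rhesus: str
    seq_mouse: str
    gene_id: str = ""
    single_syntenic_block: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.seq_human)
        if not (len(self.seq_rhesus) == len(self.seq_mouse) == n):
            raise AlignmentError(
                f"{self.intron_id}: unequal sequence lengths "
                f"({n}, {len(self.seq_rhesus)}, {len(self.seq_mouse)})"
            )
        for name, s in (
            ("human", self.seq_human),
            ("rhesus", self.seq_rhesus),
            ("mouse", self.seq_mouse),
        ):
            bad = set(s) - ALLOWED_CHARS
            if bad:
                raise AlignmentError(f"{self.intron_id}/{name}: unknown characters {sorted(bad)}")
        if self.strand not in "+-":
            raise AlignmentError(f"{self.intron_id}: strand must be + or -")
        ungapped = n - self.seq_human.count("-")
        if self.end - self.start != ungapped:
            raise AlignmentError(
                f"{self.intron_id}: end-start ({self.end - self.start}) != "
                f"ungapped human length ({ungapped})"
            )

    @property
    def length(self) -> int:
        return len(self.seq_human)

    def codes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            seq_to_codes(self.seq_human),
            seq_to_codes(self.seq_rhesus),
            seq_to_codes(self.seq_mouse),
        )

    def column_mask(self) -> np.ndarray:
        """Boolean mask of unambiguous columns (all three species A/C/G/T)."""
        h, r, m = self.codes()
        return (h < 4) & (r < 4) & (m < 4)


def count_unambiguous_sites(aln: TripletAlignment) -> int:
    """Number of columns where all three species carry a plain base."""
    return int(aln.column_mask().sum())


def filter_introns(
    alignments: Iterable[TripletAlignment],
    min_unambiguous: int = 1000,
    require_syntenic: bool = True,
) -> tuple[list[TripletAlignment], dict[str, int]]:
    """Length/synteny filter.

    Keeps alignments with at least ``min_unambiguous`` unambiguous columns
    that (when ``require_syntenic``) fall within a single syntenic alignment
    block.  Returns the kept records and a per-reason rejection report.
    """
    kept: list[TripletAlignment] = []
    report = {"kept": 0, "short": 0, "not_syntenic": 0}
    for aln in alignments:
        if require_syntenic and not aln.single_syntenic_block:
            report["not_syntenic"] += 1
        elif count_unambiguous_sites(aln) < min_unambiguous:
            report["short"] += 1
        else:
            kept.append(aln)
            report["kept"] += 1
    return kept, report


# ---------------------------------------------------------------------------
# FASTA triplet format
#
#   >human|chr1:100-1600 intron=I0001 gene=G0001 strand=+ syntenic=1
#   ACGT...
#   >rhesus|I0001
#   ...
#   >mouse|I0001
#   ...
# ---------------------------------------------------------------------------


def _human_header(aln: TripletAlignment) -> str:
    return (
        f"human|{aln.chrom}:{aln.start}-{aln.end} intron={aln.intron_id} "
        f"gene={aln.gene_id} strand={aln.strand} "
        f"syntenic={int(aln.single_syntenic_block)}"
    )


def write_alignments(
    alignments: Iterable[TripletAlignment],
    path,
    format: Literal["fasta-triplet", "maf-like"] = "fasta-triplet",
) -> None:
    with open(path, "w") as fh:
        if format == "fasta-triplet":
            records = []
            for aln in alignments:
                records.append(SeqRecord(Seq(aln.seq_human), id=_human_header(aln).split()[0],
                                         description=" ".join(_human_header(aln).split()[1:])))
                records.append(SeqRecord(Seq(aln.seq_rhesus), id=f"rhesus|{aln.intron_id}",
                                         description=""))
                records.append(SeqRecord(Seq(aln.seq_mouse), id=f"mouse|{aln.intron_id}",
                                         description=""))
            SeqIO.write(records, fh, "fasta")
        elif format == "maf-like":
            for aln in alignments:
                fh.write(
                    f"a intron={aln.intron_id} gene={aln.gene_id} chrom={aln.chrom} "
                    f"start={aln.start} end={aln.end} strand={aln.strand} "
                    f"syntenic={int(aln.single_syntenic_block)}\n"
                )
                fh.write(f"s human {aln.seq_human}\n")
                fh.write(f"s rhesus {aln.seq_rhesus}\n")
                fh.write(f"s mouse {aln.seq_mouse}\n\n")
        else:
            raise ValueError(f"unknown format: {format!r}")


def _parse_kv(fields: list[str]) -> dict[str, str]:
    return dict(f.split("=", 1) for f in fields if "=" in f)


def read_alignments(
    path, format: Literal["fasta-triplet", "maf-like"] = "fasta-triplet"
) -> Iterator[TripletAlignment]:
    """Stream validated :class:`TripletAlignment` records from ``path``.

    Malformed records raise :class:`AlignmentError` naming the record.
    """
    if format == "fasta-triplet":
        yield from _read_fasta_triplet(path)
    elif format == "maf-like":
        yield from _read_maf_like(path)
    else:
        raise ValueError(f"unknown format: {format!r}")


def _read_fasta_triplet(path) -> Iterator[TripletAlignment]:
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) % 3:
        raise AlignmentError(f"{path}: record count {len(records)} not a multiple of 3")
    seen: set[str] = set()
    for i in range(0, len(records), 3):
        hum, rhe, mou = records[i : i + 3]
        if not hum.id.startswith("human|"):
            raise AlignmentError(f"{path}: record {i}: expected human record, got {hum.id!r}")
        loc = hum.id.split("|", 1)[1]
        chrom, rng = loc.rsplit(":", 1)
        start, end = (int(x) for x in rng.split("-"))
        kv = _parse_kv(hum.description.split())
        intron_id = kv.get("intron", loc)
        if intron_id in seen:
            raise AlignmentError(f"{path}: duplicate intron id {intron_id!r}")
        seen.add(intron_id)
        for rec, species in ((rhe, "rhesus"), (mou, "mouse")):
            if not rec.id.startswith(species):
                raise AlignmentError(f"{path}: intron {intron_id}: expected {species} record")
        yield TripletAlignment(
            intron_id=intron_id,
            chrom=chrom,
            start=start,
            end=end,
            strand=kv.get("strand", "+"),
            seq_human=str(hum.seq).upper(),
            seq_rhesus=str(rhe.seq).upper(),
            seq_mouse=str(mou.seq).upper(),
            gene_id=kv.get("gene", ""),
            single_syntenic_block=bool(int(kv.get("syntenic", "1"))),
        )


def _read_maf_like(path) -> Iterator[TripletAlignment]:
    seen: set[str] = set()
    with open(path) as fh:
        block: dict[str, str] = {}
        meta: dict[str, str] = {}
        lineno = 0

        def flush():
            if not meta:
                return None
            for sp in ("human", "rhesus", "mouse"):
                if sp not in block:
                    raise AlignmentError(f"{path}:{lineno}: block missing {sp} sequence")
            intron_id = meta["intron"]
            if intron_id in seen:
                raise AlignmentError(f"{path}:{lineno}: duplicate intron id {intron_id!r}")
            seen.add(intron_id)
            return TripletAlignment(
                intron_id=intron_id,
                chrom=meta["chrom"],
                start=int(meta["start"]),
                end=int(meta["end"]),
                strand=meta.get("strand", "+"),
                seq_human=block["human"].upper(),
                seq_rhesus=block["rhesus"].upper(),
                seq_mouse=block["mouse"].upper(),
                gene_id=meta.get("gene", ""),
                single_syntenic_block=bool(int(meta.get("syntenic", "1"))),
            )

        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if line.startswith("a "):
                rec = flush()
                if rec is not None:
                    yield rec
                meta = _parse_kv(line.split()[1:])
                block = {}
            elif line.startswith("s "):
                _, sp, seq = line.split(maxsplit=2)
                block[sp] = seq
        rec = flush()
        if rec is not None:
            yield rec


# ---------------------------------------------------------------------------
# Genomic interval tracks
# ---------------------------------------------------------------------------


class TrackError(ValueError):
    pass


@dataclass
class GenomicTrack:
    """Sorted per-chromosome interval track with arbitrary payload columns.

    ``intervals`` is a DataFrame with at least columns chrom/start/end
    (0-based half-open).  Window tracks (methylation, recombination) must be
    non-overlapping within a chromosome; annotation tracks (CGI, DHS) may
    overlap.
    """

    intervals: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        df = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise TrackError(f"track {self.name!r}: missing column {col!r}")
        if (df["end"] <= df["start"]).any():
            raise TrackError(f"track {self.name!r}: empty or inverted interval")
        if "methylation" in df.columns:
            m = df["methylation"].dropna()
            if ((m < 0) | (m > 1)).any():
                raise TrackError(f"track {self.name!r}: methylation outside [0, 1]")
        grouped = df.groupby("chrom", sort=False)
        for chrom, sub in grouped:
            if not sub["start"].is_monotonic_increasing:
                raise TrackError(f"track {self.name!r}: {chrom} not sorted by start")
        self._by_chrom = {chrom: sub.reset_index(drop=True) for chrom, sub in grouped}

    def overlap_query(
        self, chrom: str, start: int, end: int, mode: Literal["contained", "any"] = "any"
    ) -> pd.DataFrame:
        """Intervals fully inside (``contained``) or intersecting (``any``)
        the half-open query ``[start, end)``."""
        sub = self._by_chrom.get(chrom)
        if sub is None:
            return self.intervals.iloc[0:0]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if mode == "contained":
            sel = (starts >= start) & (ends <= end)
        elif mode == "any":
            sel = (starts < end) & (ends > start)
        else:
            raise ValueError(f"unknown mode: {mode!r}")
        return sub[sel]

    @classmethod
    def read_bed(cls, path, columns: tuple[str, ...] = (), name: str = "") -> "GenomicTrack":
        """Read a BED-like file; ``columns`` names the payload columns after
        chrom/start/end."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df.columns = ["chrom", "start", "end", *columns][: df.shape[1]]
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        return cls(df, name=name or str(path))

    def write_bed(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)
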