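"""Sequence, interval and gene-annotation primitives.

All coordinates inside the package are 0-based half-open (BED convention);
GFF3 1-based inclusive coordinates are converted at the I/O boundary.
The nucleotide alphabet is {A, C, G, T, N}; lower-case input is upper-cased
on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

ALPHABET = "ACGTN"
_VALID = set(ALPHABET)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# integer encoding used throughout: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


class ParseError(ValueError):
    """Malformed input file; message carries line/record context."""


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N. Raises on other symbols."""
    bad = set(seq.upper()) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide symbol(s): {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def at_fraction(seq: str) -> float:
    """(#A + #T) / (length - #N); undefined (error) for empty or all-N."""
    if not seq:
        raise ValueError("at_fraction of empty sequence is undefined")
    s = seq.upper()
    n_n = s.count("N")
    denom = len(s) - n_n
    if denom == 0:
        raise ValueError("at_fraction undefined: all bases are N")
    return (s.count("A") + s.count("T")) / denom


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    rank: int | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Genome:
    """Chromosome name -> upper-case nucleotide string."""

    chromosomes: dict[str, str]

    def __post_init__(self):
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"chromosome {name!r} has invalid symbols {sorted(bad)}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def fetch(self, iv: Interval) -> str:
        return self.chromosomes[iv.chrom][iv.start:iv.end]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


@dataclass
class SeqRecord:
    id: str
    seq: str
    source_interval: Interval | None = None

    def __post_init__(self):
        self.seq = self.seq.upper()
        if self.source_interval is not None:
            if len(self.seq) != self.source_interval.length:
                raise ValueError(
                    f"record {self.id}: sequence length {len(self.seq)} != "
                    f"interval length {self.source_interval.length}"
                )


@dataclass
class SequenceSet:
    """Ordered collection of records with a role tag."""

    records: list[SeqRecord]
    role: str = "foreground"  # foreground | background | calibration

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in SequenceSet")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]


@dataclass
class PeakSet:
    """Ranked peak intervals (rank 1 = top-scoring)."""

    intervals: list[Interval]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def extract(self, genome: Genome, role: str = "foreground") -> SequenceSet:
        recs = [
            SeqRecord(f"peak_{iv.rank}", genome.fetch(iv), iv)
            for iv in self.intervals
        ]
        return SequenceSet(recs, role=role)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: Interval
    strand: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> dict[str, str]:
    """Parse a FASTA file to an ordered {id: upper-case sequence} dict.

    Raises ParseError (with line number) on a sequence line before the first
    header, a duplicate id, or an empty record.
    """
    seqs: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    if not chunks:
                        raise ParseError(
                            f"{path}: empty record {current!r} before line {lineno}"
                        )
                    seqs[current] = "".join(chunks).upper()
                current = line[1:].split()[0] if len(line) > 1 else ""
                if not current:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                if current in seqs:
                    raise ParseError(
                        f"{path}:{lineno}: duplicate record id {current!r}"
                    )
                chunks = []
            else:
                if current is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunks.append(line.strip())
    if current is not None:
        if not chunks:
            raise ParseError(f"{path}: empty record {current!r} at end of file")
        seqs[current] = "".join(chunks).upper()
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    return seqs


def read_genome(path) -> Genome:
    return Genome(read_fasta(path))


def read_sequence_set(path, role: str = "foreground") -> SequenceSet:
    seqs = read_fasta(path)
    return SequenceSet([SeqRecord(k, v) for k, v in seqs.items()], role=role)


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bed(path, genome: Genome) -> PeakSet:
    """Read BED3/BED5 intervals and rank them by descending score.

    Ties (and missing scores) are broken by (chrom, start) ascending, so the
    odd/even cross-validation split is deterministic.
    """
    raw: list[Interval] = []
    with open(path) as fh:
        for idx, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: record {idx}: fewer than 3 columns")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ParseError(f"{path}: record {idx}: bad coordinates") from exc
            if chrom not in genome:
                raise ParseError(
                    f"{path}: record {idx}: unknown chromosome {chrom!r}"
                )
            if not (0 <= start < end <= genome.length(chrom)):
                raise ParseError(
                    f"{path}: record {idx}: interval "
                    f"{start}-{end} outside {chrom} (len {genome.length(chrom)})"
                )
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            raw.append(Interval(chrom, start, end, score=score))
    if not raw:
        raise ParseError(f"{path}: no intervals")
    return rank_peaks(raw)


def rank_peaks(intervals: list[Interval]) -> PeakSet:
    """Assign 1-based ranks by descending score, ties by (chrom, start)."""
    order = sorted(
        intervals,
        key=lambda iv: (
            -(iv.score if iv.score is not None else float("-inf")),
            iv.chrom,
            iv.start,
        ),
    )
    ranked = [
        Interval(iv.chrom, iv.start, iv.end, score=iv.score, rank=i + 1)
        for i, iv in enumerate(order)
    ]
    return PeakSet(ranked)


def write_bed(path, intervals: Iterable[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score}\n")


def read_gff_genes(path) -> list[GeneModel]:
    """Extract features of type 'gene' from a GFF3 file.

    GFF 1-based inclusive coordinates are converted to 0-based half-open.
    A gene without an ID attribute or with strand '.' is an error: the
    strand orients upstream-region extraction.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != "gene":
                continue
            gene_id = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene without ID attribute")
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            if strand not in "+-":
                raise ParseError(
                    f"{path}:{lineno}: gene {gene_id}: strand is required"
                )
            seen.add(gene_id)
            iv = Interval(chrom, int(start) - 1, int(end))
            genes.append(GeneModel(gene_id, iv, strand))
    return genes


def write_gff_genes(path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.interval.chrom}\tmultimotif\tgene\t{g.interval.start + 1}\t"
                f"{g.interval.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
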