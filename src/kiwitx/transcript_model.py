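"""Transcript/gene data model, GTF/FASTA/BED I/O, and interval algebra.

Coordinates follow the GTF convention throughout: 1-based, inclusive on both
ends. BED input (0-based half-open) is converted at the boundary. Adjacent
exons (a zero-length gap) are treated as malformed input rather than being
merged silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "IntronLengthSummary",
    "GtfParseError",
    "parse_gtf",
    "write_gtf",
    "read_bed",
    "load_genome",
    "write_fasta",
    "reverse_complement",
    "derive_introns",
    "overlap_length",
    "genomic_distance",
    "summarize_intron_lengths",
]

PREDICTED = "predicted"
ASSEMBLED = "assembled"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    """Raised for malformed annotation lines; names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end < start ({self.end} < {self.start})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    """An exon chain on one strand of one sequence.

    Exons are stored sorted by start and must be non-overlapping and
    non-adjacent (every intron has length >= 1).
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    source: str = ASSEMBLED
    biotype: str = "unassessed"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        seq_ids = {e.seq_id for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(seq_ids) > 1 or len(strands) > 1:
            raise ValueError(
                f"{self.transcript_id}: exons span multiple sequences/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {a}..{b}"
                )
            if b.start == a.end + 1:
                raise ValueError(
                    f"{self.transcript_id}: adjacent exons at {a.end}/{b.start} "
                    "(invalid exon chain)"
                )

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene needs >=1 transcript")

    @property
    def span(self) -> GenomicInterval:
        t0 = self.transcripts[0]
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(t0.seq_id, start, end, t0.strand)


@dataclass
class IntronLengthSummary:
    count: int
    mean_bp: float
    median_bp: float
    histogram: list[tuple[str, int]]
    defined: bool = True


# ---------------------------------------------------------------------------
# interval algebra


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 if disjoint or on different
    sequences. Strand is ignored."""
    if a.seq_id != b.seq_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def genomic_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp strictly between two intervals; 0 when they overlap or
    touch; infinite across sequences."""
    if a.seq_id != b.seq_id:
        return float("inf")
    if overlap_length(a, b) > 0:
        return 0
    return max(a.start, b.start) - min(a.end, b.end) - 1


def derive_introns(t: Transcript) -> list[GenomicInterval]:
    """Gaps between consecutive exons; empty for single-exon transcripts."""
    introns = []
    for a, b in zip(t.exons, t.exons[1:]):
        introns.append(
            GenomicInterval(t.seq_id, a.end + 1, b.start - 1, t.strand)
        )
    return introns


def summarize_intron_lengths(
    transcripts: Iterable[Transcript],
    bins: Sequence[int] = (100, 200, 500, 1000, 2000, 5000),
) -> IntronLengthSummary:
    lengths = [
        i.length for t in transcripts for i in derive_introns(t)
    ]
    if not lengths:
        return IntronLengthSummary(0, float("nan"), float("nan"), [], defined=False)
    arr = np.asarray(lengths)
    edges = [0, *bins, np.inf]
    hist = []
    for lo, hi in zip(edges, edges[1:]):
        label = f"<= {hi}" if np.isfinite(hi) else f"> {lo}"
        hist.append((label, int(((arr > lo) & (arr <= hi)).sum())))
    return IntronLengthSummary(
        count=len(lengths),
        mean_bp=float(arr.mean()),
        median_bp=float(np.median(arr)),
        histogram=hist,
    )


# ---------------------------------------------------------------------------
# GTF I/O

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _diagnose_gtf(path: str) -> int:
    """Scan a GTF file, raising GtfParseError naming the first bad line;
    returns the number of exon features."""
    n_exons = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"line {lineno}: expected 9 fields, got {len(fields)}")
            if fields[2] != "exon":
                continue
            n_exons += 1
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if end < start:
                raise GtfParseError(f"line {lineno}: end < start ({end} < {start})")
            attrs = dict(_ATTR_RE.findall(fields[8]))
            for key in ("gene_id", "transcript_id"):
                if key not in attrs:
                    raise GtfParseError(f"line {lineno}: missing required attribute {key}")
    return n_exons


def parse_gtf(path: str, source_tag: str = ASSEMBLED) -> list[GeneModel]:
    """Read exon features from a GTF file into GeneModels.

    Every exon feature must carry ``gene_id`` and ``transcript_id``
    attributes; exons are grouped into transcripts and transcripts into
    genes, and exon lists are sorted. Malformed lines raise
    :class:`GtfParseError` naming the line number.
    """
    import gffutils

    if _diagnose_gtf(path) == 0:
        return []
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - caught by _diagnose_gtf first
        raise GtfParseError(f"{path}: {exc}") from exc

    by_transcript: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    order: list[str] = []
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        if tid not in by_transcript:
            by_transcript[tid] = []
            tx_gene[tid] = gid
            order.append(tid)
        by_transcript[tid].append(
            GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand or ".")
        )

    genes: dict[str, list[Transcript]] = {}
    gene_order: list[str] = []
    for tid in order:
        tx = Transcript(
            transcript_id=tid,
            gene_id=tx_gene[tid],
            exons=by_transcript[tid],
            source=source_tag,
        )
        if tx.gene_id not in genes:
            genes[tx.gene_id] = []
            gene_order.append(tx.gene_id)
        genes[tx.gene_id].append(tx)
    return [GeneModel(gid, genes[gid]) for gid in gene_order]


def write_gtf(models: Iterable[GeneModel], path: str, source: str = "kiwitx",
              extra_attrs: dict[str, dict[str, str]] | None = None) -> None:
    """Write exon features; ``extra_attrs`` maps transcript_id to extra
    key/value attributes (e.g. a biotype label)."""
    extra_attrs = extra_attrs or {}
    with open(path, "w") as fh:
        for gene in models:
            for tx in gene.transcripts:
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                for k, v in extra_attrs.get(tx.transcript_id, {}).items():
                    attrs += f' {k} "{v}";'
                for exon in tx.exons:
                    fh.write(
                        f"{exon.seq_id}\t{source}\texon\t{exon.start}\t{exon.end}"
                        f"\t.\t{exon.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# BED / FASTA


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED intervals (0-based half-open) into 1-based inclusive form."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: expected >=3 BED fields")
            seq_id, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            out.append(GenomicInterval(seq_id, start0 + 1, end0, strand))
    return out


def load_genome(path: str):
    """Open a FASTA file as a mapping of sequence name to sequence."""
    from pyfaidx import Fasta

    return Fasta(path, as_raw=True, sequence_always_upper=True)


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
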