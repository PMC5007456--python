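"""ORF finding, coding-potential scoring, and the lncRNA / novel-gene gates.

The coding-potential score is a transparent length-based surrogate whose
sign convention matches the published cutoffs (score > 0 coding-like,
0 > score >= -1 "weak noncoding", score < -1 "strong noncoding"). Scores
from an external classifier can be supplied as an override table and are
used verbatim when present.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from kiwitx.transcript_model import (
    GeneModel,
    GenomicInterval,
    PREDICTED,
    Transcript,
    genomic_distance,
    overlap_length,
    reverse_complement,
)

__all__ = [
    "OrfResult",
    "CodingAssessment",
    "spliced_sequence",
    "find_longest_orf",
    "coding_score",
    "gate_lncrna",
    "gate_novel_gene",
    "assess_transcript",
    "group_novel_genes",
    "read_score_table",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

# gate labels
CODING = "coding"
WEAK_NONCODING = "weak_noncoding"
STRONG_NONCODING = "strong_noncoding"
TOO_SHORT = "too_short"
PREDICTED_MODEL = "predicted_model"

MIN_LNCRNA_LENGTH = 200  # transcripts shorter than this are discarded
ORF_GATE_NT = 300        # lncRNA needs ORF < 300 nt; novel gene needs > 300 nt
NOVEL_GENE_MIN_DISTANCE = 500  # bp to the closest predicted gene model


@dataclass(frozen=True)
class OrfResult:
    start_offset: int  # 0-based offset in the spliced transcript sequence
    length_nt: int     # includes the stop codon when complete
    frame: int
    complete: bool


@dataclass
class CodingAssessment:
    transcript_id: str
    score: float
    orf: OrfResult
    label: str


NO_ORF = OrfResult(start_offset=0, length_nt=0, frame=0, complete=False)


def spliced_sequence(t: Transcript, genome: Mapping[str, str]) -> str:
    """Concatenate exon sequences 5'->3' (reverse-complemented on strand -)."""
    try:
        chrom = genome[t.seq_id]
    except KeyError:
        raise KeyError(f"{t.transcript_id}: sequence {t.seq_id!r} not in genome")
    n = len(chrom)
    parts = []
    for exon in t.exons:
        if exon.end > n:
            raise ValueError(
                f"{t.transcript_id}: exon {exon.start}-{exon.end} exceeds "
                f"sequence {t.seq_id} length {n}"
            )
        parts.append(str(chrom[exon.start - 1 : exon.end]))
    seq = "".join(parts).upper()
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq


def find_longest_orf(seq: str) -> OrfResult:
    """Longest ATG-initiated, stop-terminated ORF over the three sense frames.

    Ties are broken by the smaller start offset. When no complete ORF exists
    the longest ATG-to-end open stretch is returned with ``complete=False``;
    a sequence with no ATG yields a zero-length result.
    """
    seq = seq.upper()
    n = len(seq)

    def better(cand: OrfResult, incumbent: OrfResult) -> bool:
        return cand.length_nt > incumbent.length_nt or (
            cand.length_nt == incumbent.length_nt
            and cand.start_offset < incumbent.start_offset
        )

    best_complete = NO_ORF
    best_open = NO_ORF
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                cand = OrfResult(start, pos + 3 - start, frame, complete=True)
                if better(cand, best_complete):
                    best_complete = cand
                start = None
        if start is not None:
            cand = OrfResult(start, n - start, frame, complete=False)
            if better(cand, best_open):
                best_open = cand
    if best_complete.length_nt > 0:
        return best_complete
    if best_open.length_nt > 0:
        return best_open
    return NO_ORF


def coding_score(
    t: Transcript,
    orf: OrfResult,
    override: Optional[Mapping[str, float]] = None,
) -> float:
    """Length-based coding-potential surrogate.

    s = (L/300 - 1) + (L/T - 0.5) + (0.25 if complete else -0.25)

    with L the ORF length (nt) and T the spliced transcript length. The
    score is 0 at the design boundary (complete 300-nt ORF covering half the
    transcript) and decreases as the ORF shrinks in absolute and relative
    terms. An override entry for the transcript wins unconditionally.
    """
    if override is not None and t.transcript_id in override:
        return float(override[t.transcript_id])
    length = t.length
    s = (orf.length_nt / ORF_GATE_NT - 1.0) + (orf.length_nt / length - 0.5)
    s += 0.25 if orf.complete else -0.25
    return s


def gate_lncrna(t: Transcript, a: CodingAssessment) -> str:
    """Apply the lncRNA candidacy gate.

    Transcripts from the predicted gene models and transcripts shorter than
    200 bp are discarded up front; the rest are lncRNA when the coding score
    is < 0 and the ORF is < 300 nt, split into weak (-1 <= s < 0) and strong
    (s < -1) noncoding; everything else is coding.
    """
    if t.source == PREDICTED:
        return PREDICTED_MODEL
    if t.length < MIN_LNCRNA_LENGTH:
        return TOO_SHORT
    if a.score < 0 and a.orf.length_nt < ORF_GATE_NT:
        return WEAK_NONCODING if a.score >= -1 else STRONG_NONCODING
    return CODING


def assess_transcript(
    t: Transcript,
    genome: Mapping[str, str],
    override: Optional[Mapping[str, float]] = None,
) -> CodingAssessment:
    """ORF + score + gate label for one transcript."""
    if t.strand == ".":
        # unstranded: no ORF search; score from the empty ORF
        orf = NO_ORF
    else:
        orf = find_longest_orf(spliced_sequence(t, genome))
    a = CodingAssessment(t.transcript_id, 0.0, orf, "unassessed")
    a.score = coding_score(t, orf, override)
    a.label = gate_lncrna(t, a)
    return a


def _min_distance_to_genes(
    span: GenomicInterval, gene_spans: Iterable[GenomicInterval]
) -> float:
    dists = [genomic_distance(span, g) for g in gene_spans]
    return min(dists) if dists else float("inf")


def gate_novel_gene(
    t: Transcript,
    a: CodingAssessment,
    predicted_genes: list[GeneModel],
) -> bool:
    """Novel protein-coding call: intergenic with > 500 bp to the closest
    predicted gene span, ORF > 300 nt, and coding score > 0."""
    if t.source == PREDICTED:
        return False
    dist = _min_distance_to_genes(t.span, (g.span for g in predicted_genes))
    return (
        dist > NOVEL_GENE_MIN_DISTANCE
        and a.orf.length_nt > ORF_GATE_NT
        and a.score > 0
    )


def group_novel_genes(novel_transcripts: list[Transcript]) -> list[list[Transcript]]:
    """Group novel transcripts into genes by span overlap on the same
    seq_id/strand (single-linkage)."""
    groups: list[list[Transcript]] = []
    spans: list[GenomicInterval] = []
    for t in sorted(novel_transcripts, key=lambda x: (x.seq_id, x.span.start)):
        placed = False
        for i, span in enumerate(spans):
            if (
                span.strand == t.strand
                and overlap_length(span, t.span) > 0
            ):
                groups[i].append(t)
                spans[i] = GenomicInterval(
                    span.seq_id,
                    min(span.start, t.span.start),
                    max(span.end, t.span.end),
                    span.strand,
                )
                placed = True
                break
        if not placed:
            groups.append([t])
            spans.append(t.span)
    return groups


def read_score_table(path: str) -> dict[str, float]:
    """External coding-potential scores: TSV with header
    (transcript_id, score)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "transcript_id" not in reader.fieldnames \
                or "score" not in reader.fieldnames:
            raise ValueError(f"{path}: expected header with transcript_id and score")
        for row in reader:
            try:
                out[row["transcript_id"]] = float(row["score"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric score for {row.get('transcript_id')}"
                ) from None
    return out
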