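"""Anatomical classification of lncRNAs and the category summaries.

Categories are multi-label: one lncRNA may simultaneously be intergenic
(lincRNA), overlap a coding gene region, lie inside an intron, and/or run
antisense to another transcript. A deterministic primary label (precedence
antisense > intronic > overlapping > lincRNA > other) is provided for
single-label reports.

Reference sets differ by rule: the lincRNA distance criterion is measured
against predicted gene-model spans only, while intronic containment and
antisense overlap are evaluated against all coding transcripts (predicted
plus novel) and, for antisense, against the other lncRNAs as well.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from kiwitx.transcript_model import (
    GeneModel,
    GenomicInterval,
    Transcript,
    derive_introns,
    genomic_distance,
    overlap_length,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LncRNARecord",
    "PairRecord",
    "AnatomySummary",
    "LINCRNA",
    "OVERLAPPING",
    "ANTISENSE",
    "INTRONIC",
    "OTHER",
    "classify_anatomy",
    "classify_all",
    "detect_pairs",
    "annotate_repeat_overlap",
    "summarize_anatomy",
    "primary_label",
]

LINCRNA = "lincRNA"
OVERLAPPING = "overlapping"
ANTISENSE = "antisense"
INTRONIC = "intronic"
OTHER = "other"

PRECEDENCE = (ANTISENSE, INTRONIC, OVERLAPPING, LINCRNA, OTHER)

LINCRNA_MIN_DISTANCE = 500   # bp to the closest predicted gene span
ANTISENSE_MIN_OVERLAP = 50   # exonic overlap must exceed this (strict)


@dataclass
class LncRNARecord:
    transcript_id: str
    categories: set[str]
    host_transcript: Optional[str] = None
    host_transcripts: list[str] = field(default_factory=list)
    antisense_partners: list[tuple[str, str]] = field(default_factory=list)
    repeat_overlap: bool = False


@dataclass(frozen=True)
class PairRecord:
    lncrna_id: str
    partner_id: str
    pair_type: str        # intronic_pair | antisense_pair
    partner_class: str    # coding | noncoding


@dataclass
class AnatomySummary:
    counts: dict[str, int]
    exon_histogram: dict[str, dict[int, int]]
    median_length: float
    median_length_by_category: dict[str, float]
    repeat_fraction: float
    total: int


def _tree(intervals: Iterable[tuple[GenomicInterval, object]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv, payload in intervals:
        trees[iv.seq_id].addi(iv.start, iv.end + 1, (iv, payload))
    return trees


def _exonic_overlap(a: Transcript, b: Transcript) -> int:
    return sum(
        overlap_length(ea, eb) for ea in a.exons for eb in b.exons
    )


class AnatomyContext:
    """Pre-indexed reference annotation for repeated classification calls."""

    def __init__(
        self,
        predicted_genes: Sequence[GeneModel],
        coding_transcripts: Sequence[Transcript],
        noncoding_transcripts: Sequence[Transcript] = (),
    ):
        self.predicted_spans = [g.span for g in predicted_genes]
        self.predicted_by_seq: dict[str, list[GenomicInterval]] = defaultdict(list)
        for s in self.predicted_spans:
            self.predicted_by_seq[s.seq_id].append(s)

        # coding gene spans (predicted + novel) for the "overlapping" rule
        gene_bounds: dict[tuple[str, str], list[int]] = {}
        for t in coding_transcripts:
            key = (t.seq_id, t.gene_id)
            b = gene_bounds.setdefault(key, [t.span.start, t.span.end, 0])
            b[0] = min(b[0], t.span.start)
            b[1] = max(b[1], t.span.end)
        self.gene_span_trees = _tree(
            (GenomicInterval(seq, b[0], b[1]), gid)
            for (seq, gid), b in gene_bounds.items()
        )

        self.coding_tx_trees = _tree((t.span, t) for t in coding_transcripts)
        self.noncoding_tx_trees = _tree((t.span, t) for t in noncoding_transcripts)

        # introns of coding transcripts, for intronic containment
        self.intron_trees = _tree(
            (intron, t)
            for t in coding_transcripts
            for intron in derive_introns(t)
        )

    def min_predicted_distance(self, span: GenomicInterval) -> float:
        spans = self.predicted_by_seq.get(span.seq_id, [])
        if not spans:
            return float("inf")
        return min(genomic_distance(span, s) for s in spans)


def classify_anatomy(
    lnc: Transcript,
    predicted_genes: Sequence[GeneModel],
    coding_transcripts: Sequence[Transcript],
    noncoding_transcripts: Sequence[Transcript] = (),
    context: Optional[AnatomyContext] = None,
) -> LncRNARecord:
    """Multi-label anatomical classification of one gated lncRNA."""
    ctx = context or AnatomyContext(
        predicted_genes, coding_transcripts, noncoding_transcripts
    )
    span = lnc.span
    categories: set[str] = set()
    record = LncRNARecord(lnc.transcript_id, categories)

    if ctx.min_predicted_distance(span) > LINCRNA_MIN_DISTANCE:
        categories.add(LINCRNA)

    for hit in ctx.gene_span_trees.get(span.seq_id, IntervalTree()).overlap(
        span.start, span.end + 1
    ):
        if hit.data[1] != lnc.gene_id:
            categories.add(OVERLAPPING)
            break

    if lnc.strand == ".":
        logger.warning(
            "%s: unknown strand; antisense/intronic rules skipped",
            lnc.transcript_id,
        )
    else:
        # antisense: exonic overlap > 50 bp with an opposite-strand transcript
        for trees, klass in (
            (ctx.coding_tx_trees, "coding"),
            (ctx.noncoding_tx_trees, "noncoding"),
        ):
            for hit in trees.get(span.seq_id, IntervalTree()).overlap(
                span.start, span.end + 1
            ):
                partner: Transcript = hit.data[1]
                if partner.transcript_id == lnc.transcript_id:
                    continue
                if partner.strand == lnc.strand or partner.strand == ".":
                    continue
                if _exonic_overlap(lnc, partner) > ANTISENSE_MIN_OVERLAP:
                    categories.add(ANTISENSE)
                    record.antisense_partners.append(
                        (partner.transcript_id, klass)
                    )

        # intronic: span entirely within a single intron of a coding transcript
        for hit in ctx.intron_trees.get(span.seq_id, IntervalTree()).overlap(
            span.start, span.end + 1
        ):
            intron, host = hit.data
            if intron.start <= span.start and span.end <= intron.end:
                categories.add(INTRONIC)
                record.host_transcripts.append(host.transcript_id)

    record.antisense_partners.sort()
    record.host_transcripts = sorted(set(record.host_transcripts))
    if record.host_transcripts:
        record.host_transcript = record.host_transcripts[0]
    if not categories:
        categories.add(OTHER)
    return record


def classify_all(
    lnc_transcripts: Sequence[Transcript],
    predicted_genes: Sequence[GeneModel],
    coding_transcripts: Sequence[Transcript],
) -> list[LncRNARecord]:
    """Classify every gated lncRNA, letting lncRNAs serve as each other's
    antisense partners."""
    ctx = AnatomyContext(predicted_genes, coding_transcripts, lnc_transcripts)
    return [
        classify_anatomy(t, predicted_genes, coding_transcripts, context=ctx)
        for t in lnc_transcripts
    ]


def primary_label(record: LncRNARecord) -> str:
    for cat in PRECEDENCE:
        if cat in record.categories:
            return cat
    return OTHER


def detect_pairs(records: Sequence[LncRNARecord]) -> list[PairRecord]:
    """One intronic pair per (lncRNA, host transcript); one antisense pair
    per (lncRNA, qualifying opposite-strand partner)."""
    pairs: list[PairRecord] = []
    for rec in records:
        for host in rec.host_transcripts:
            pairs.append(PairRecord(rec.transcript_id, host, "intronic_pair", "coding"))
        for partner, klass in rec.antisense_partners:
            pairs.append(PairRecord(rec.transcript_id, partner, "antisense_pair", klass))
    return pairs


def annotate_repeat_overlap(
    records: Sequence[LncRNARecord],
    transcripts: Sequence[Transcript],
    repeats: Optional[Sequence[GenomicInterval]],
) -> tuple[float, bool]:
    """Flag lncRNAs whose exons overlap >= 1 repeat interval by >= 1 bp.

    Returns (fraction flagged, repeats_supplied). Without a repeat
    annotation the fraction is 0 and the flag is False.
    """
    if repeats is None or len(records) == 0:
        if repeats is None:
            logger.warning("no repeats supplied; repeat overlap set to 0")
        return 0.0, False
    trees = _tree((r, None) for r in repeats)
    by_id = {t.transcript_id: t for t in transcripts}
    hits = 0
    for rec in records:
        t = by_id[rec.transcript_id]
        tree = trees.get(t.seq_id, IntervalTree())
        rec.repeat_overlap = any(
            tree.overlap(e.start, e.end + 1) for e in t.exons
        )
        hits += rec.repeat_overlap
    return hits / len(records), True


def summarize_anatomy(
    records: Sequence[LncRNARecord],
    transcripts: Sequence[Transcript],
) -> AnatomySummary:
    by_id = {t.transcript_id: t for t in transcripts}
    counts = {cat: 0 for cat in PRECEDENCE}
    exon_hist: dict[str, dict[int, int]] = {cat: defaultdict(int) for cat in PRECEDENCE}
    exon_hist["all"] = defaultdict(int)
    lengths: dict[str, list[int]] = {cat: [] for cat in PRECEDENCE}
    all_lengths: list[int] = []
    n_repeat = 0
    for rec in records:
        t = by_id[rec.transcript_id]
        n_exons = len(t.exons)
        exon_hist["all"][n_exons] += 1
        all_lengths.append(t.length)
        n_repeat += rec.repeat_overlap
        for cat in rec.categories:
            counts[cat] += 1
            exon_hist[cat][n_exons] += 1
            lengths[cat].append(t.length)
    return AnatomySummary(
        counts=counts,
        exon_histogram={k: dict(v) for k, v in exon_hist.items()},
        median_length=float(np.median(all_lengths)) if all_lengths else float("nan"),
        median_length_by_category={
            cat: (float(np.median(v)) if v else float("nan"))
            for cat, v in lengths.items()
        },
        repeat_fraction=n_repeat / len(records) if records else 0.0,
        total=len(records),
    )
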