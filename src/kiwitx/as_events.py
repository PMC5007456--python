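"""Alternative-splicing event detection, classification, and splice-site
dinucleotide classing.

Events follow the pairwise-variation convention: for every pair of isoforms
at a locus, the two intron chains are aligned on shared splice sites
(restricted to the genomic window both transcripts span); each maximal run
of non-shared sites between two consecutive shared sites (or chain ends)
emits one event. An event's two sides are the intron sub-chains involved in
the run; identical signatures across pairs are merged, so counts reflect
unique structures, not isoform pairs.

Classification is a pure function of the signature:

* one intron per side sharing one boundary         -> alternative acceptor
  (shared donor) or alternative donor (shared acceptor), strand-corrected:
  on strand '-' the genomic right end of an intron is the donor;
* one intron vs none                               -> intron retention;
* two introns vs one intron bridging both          -> exon skipping;
* anything else (incl. multi-exon skips, mutually exclusive exons, regions
  truncated by transcript ends that fit no template) -> other.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from kiwitx.transcript_model import (
    GeneModel,
    GenomicInterval,
    Transcript,
    derive_introns,
    reverse_complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SpliceChain",
    "EventSignature",
    "ASEvent",
    "SpliceSiteRecord",
    "ALT_ACCEPTOR",
    "ALT_DONOR",
    "INTRON_RETENTION",
    "EXON_SKIPPING",
    "OTHER_EVENT",
    "extract_splice_chains",
    "enumerate_events",
    "enumerate_events_all",
    "classify_event",
    "classify_splice_sites",
    "tally_site_classes",
    "count_events_by_stage",
]

ALT_ACCEPTOR = "alt_acceptor_3p"
ALT_DONOR = "alt_donor_5p"
INTRON_RETENTION = "intron_retention"
EXON_SKIPPING = "exon_skipping"
OTHER_EVENT = "other"

EVENT_CATEGORIES = (
    ALT_ACCEPTOR,
    ALT_DONOR,
    INTRON_RETENTION,
    EXON_SKIPPING,
    OTHER_EVENT,
)

SITE_CLASSES = ("GT-AG", "GC-AG", "AT-AC", "other")
_CANONICAL_PAIRS = {("GT", "AG"): "GT-AG", ("GC", "AG"): "GC-AG", ("AT", "AC"): "AT-AC"}

Intron = tuple[int, int]


@dataclass
class SpliceChain:
    transcript_id: str
    seq_id: str
    strand: str
    introns: list[GenomicInterval]


@dataclass(frozen=True)
class EventSignature:
    """Canonical encoding of one variation region.

    ``side_a``/``side_b`` are the two alternative intron sub-chains as
    (start, end) tuples; sides are stored in lexicographic order so the
    signature is independent of which isoform contributed which side.
    """

    seq_id: str
    strand: str
    side_a: tuple[Intron, ...]
    side_b: tuple[Intron, ...]

    @staticmethod
    def make(seq_id: str, strand: str,
             s1: tuple[Intron, ...], s2: tuple[Intron, ...]) -> "EventSignature":
        a, b = sorted((tuple(s1), tuple(s2)))
        return EventSignature(seq_id, strand, a, b)

    @property
    def start(self) -> int:
        coords = [c for side in (self.side_a, self.side_b) for i in side for c in i]
        return min(coords)

    @property
    def end(self) -> int:
        coords = [c for side in (self.side_a, self.side_b) for i in side for c in i]
        return max(coords)


@dataclass
class ASEvent:
    signature: EventSignature
    category: str
    gene_id: str
    supporting_a: set[str] = field(default_factory=set)  # isoforms on side_a
    supporting_b: set[str] = field(default_factory=set)  # isoforms on side_b

    @property
    def supporting(self) -> set[str]:
        return self.supporting_a | self.supporting_b


@dataclass(frozen=True)
class SpliceSiteRecord:
    intron: GenomicInterval
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    site_class: str


def extract_splice_chains(transcripts: Iterable[Transcript]) -> list[SpliceChain]:
    return [
        SpliceChain(t.transcript_id, t.seq_id, t.strand, derive_introns(t))
        for t in transcripts
    ]


# ---------------------------------------------------------------------------
# event enumeration

# a splice site is (position, role); role "L" = intron start boundary,
# role "R" = intron end boundary, in genomic orientation
Site = tuple[int, str]


def _sites(introns: Sequence[Intron]) -> list[Site]:
    out: list[Site] = []
    for s, e in introns:
        out.append((s, "L"))
        out.append((e, "R"))
    return out


def _site_order(site: Site) -> tuple[int, int]:
    return site[0], 0 if site[1] == "R" else 1


def _pair_events(t1: Transcript, t2: Transcript) -> list[tuple[EventSignature, tuple[Intron, ...], tuple[Intron, ...]]]:
    """Variation regions between one isoform pair.

    Returns (signature, side-of-t1, side-of-t2) triples.
    """
    w0 = max(t1.span.start, t2.span.start)
    w1 = min(t1.span.end, t2.span.end)
    if w1 <= w0:
        return []
    in1 = [(i.start, i.end) for i in derive_introns(t1) if i.start >= w0 and i.end <= w1]
    in2 = [(i.start, i.end) for i in derive_introns(t2) if i.start >= w0 and i.end <= w1]
    s1, s2 = set(_sites(in1)), set(_sites(in2))
    common = s1 & s2
    merged = sorted(s1 | s2, key=_site_order)

    # split the merged chain into runs of non-common sites
    runs: list[tuple[Optional[Site], list[Site], Optional[Site]]] = []
    current: list[Site] = []
    prev_common: Optional[Site] = None
    for site in merged:
        if site in common:
            if current:
                runs.append((prev_common, current, site))
                current = []
            prev_common = site
        else:
            current.append(site)
    if current:
        runs.append((prev_common, current, None))

    out = []
    for left, run, right in runs:
        run_set = set(run)

        def side(introns: Sequence[Intron]) -> tuple[Intron, ...]:
            chosen = [
                iv for iv in introns
                if (iv[0], "L") in run_set or (iv[1], "R") in run_set
            ]
            # bridging intron: both boundaries are the flanking common sites
            if not chosen and left is not None and right is not None:
                if left[1] == "L" and right[1] == "R" and (left[0], right[0]) in introns:
                    chosen = [(left[0], right[0])]
            return tuple(sorted(chosen))

        side1, side2 = side(in1), side(in2)
        if side1 == side2:
            continue
        sig = EventSignature.make(t1.seq_id, t1.strand, side1, side2)
        out.append((sig, side1, side2))
    return out


def classify_event(sig: EventSignature) -> str:
    """Category of a variation-region signature (pure function)."""
    a, b = sig.side_a, sig.side_b
    if sig.strand not in {"+", "-"}:
        raise ValueError("event classification requires a stranded signature")
    if len(a) == 1 and len(b) == 1:
        (a0,), (b0,) = a, b
        if a0 == b0:
            raise ValueError("malformed signature: identical sides")
        if a0[0] == b0[0]:  # shared genomic left boundary
            return ALT_ACCEPTOR if sig.strand == "+" else ALT_DONOR
        if a0[1] == b0[1]:  # shared genomic right boundary
            return ALT_DONOR if sig.strand == "+" else ALT_ACCEPTOR
        return OTHER_EVENT
    if (len(a), len(b)) in ((0, 1), (1, 0)):
        return INTRON_RETENTION
    one, two = (a, b) if len(a) < len(b) else (b, a)
    if len(one) == 1 and len(two) == 2:
        (s1, e1), (s2, e2) = two
        if one[0] == (s1, e2):
            return EXON_SKIPPING
    return OTHER_EVENT


def enumerate_events(locus: GeneModel) -> list[ASEvent]:
    """All deduplicated AS events at one locus.

    Every isoform pair is compared; events with identical signatures are
    merged and their supporting isoform sets unioned. Output is ordered by
    genomic coordinate.
    """
    txs = locus.transcripts
    events: dict[EventSignature, ASEvent] = {}
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            t1, t2 = txs[i], txs[j]
            if t1.seq_id != t2.seq_id or t1.strand != t2.strand:
                continue
            for sig, side1, side2 in _pair_events(t1, t2):
                ev = events.get(sig)
                if ev is None:
                    ev = ASEvent(sig, classify_event(sig), locus.gene_id)
                    events[sig] = ev
                for side, tid in ((side1, t1.transcript_id), (side2, t2.transcript_id)):
                    if tuple(side) == sig.side_a:
                        ev.supporting_a.add(tid)
                    else:
                        ev.supporting_b.add(tid)
    return sorted(
        events.values(),
        key=lambda e: (e.signature.seq_id, e.signature.start, e.signature.end,
                       e.signature.side_a, e.signature.side_b),
    )


def enumerate_events_all(loci: Iterable[GeneModel]) -> list[ASEvent]:
    out: list[ASEvent] = []
    for locus in loci:
        if len(locus.transcripts) >= 2:
            out.extend(enumerate_events(locus))
    return out


# ---------------------------------------------------------------------------
# splice-site dinucleotide classing


def classify_splice_sites(
    chains: Iterable[SpliceChain],
    genome: Mapping[str, str],
    unique: bool = True,
) -> list[SpliceSiteRecord]:
    """Donor/acceptor dinucleotides per intron, strand-corrected.

    With ``unique=True`` (default) each genomic intron is classed once even
    when shared between isoforms.
    """
    seen: set[tuple[str, str, int, int]] = set()
    records: list[SpliceSiteRecord] = []
    for chain in chains:
        for intron in chain.introns:
            key = (chain.seq_id, chain.strand, intron.start, intron.end)
            if unique:
                if key in seen:
                    continue
                seen.add(key)
            if intron.length < 4:
                logger.warning(
                    "intron %s:%d-%d shorter than 4 bp; classed as other",
                    chain.seq_id, intron.start, intron.end,
                )
                records.append(SpliceSiteRecord(intron, "", "", "other"))
                continue
            seq = str(genome[chain.seq_id][intron.start - 1 : intron.end]).upper()
            if chain.strand == "-":
                seq = reverse_complement(seq)
            donor, acceptor = seq[:2], seq[-2:]
            site_class = _CANONICAL_PAIRS.get((donor, acceptor), "other")
            records.append(SpliceSiteRecord(intron, donor, acceptor, site_class))
    return records


def tally_site_classes(records: Sequence[SpliceSiteRecord]) -> dict[str, int]:
    counts = Counter(r.site_class for r in records)
    return {cls: counts.get(cls, 0) for cls in SITE_CLASSES}


# ---------------------------------------------------------------------------
# per-stage event counting


def count_events_by_stage(
    events: Sequence[ASEvent],
    stage_fpkm: Mapping[str, Mapping[str, float]],
    stages: Sequence[str],
    threshold: float = 0.1,
) -> dict[str, dict[str, int]]:
    """Count an event at a stage when both of its sides have at least one
    supporting isoform expressed (FPKM >= threshold) at that stage.

    ``stage_fpkm`` maps stage -> {transcript_id -> FPKM}.
    """
    table: dict[str, dict[str, int]] = {
        stage: {cat: 0 for cat in EVENT_CATEGORIES} for stage in stages
    }
    for ev in events:
        for stage in stages:
            expr = stage_fpkm[stage]
            on_a = any(expr.get(t, 0.0) >= threshold for t in ev.supporting_a)
            on_b = any(expr.get(t, 0.0) >= threshold for t in ev.supporting_b)
            if on_a and on_b:
                table[stage][ev.category] += 1
    return table
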