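"""Seeded simulation of a toy genome, annotation, and count matrix with a
planted ground-truth manifest.

The generator emulates the post-alignment state of a merged fruit
transcriptome: predicted coding gene models, assembled isoforms realizing
each alternative-splicing category, noncoding transcripts of each anatomical
category (including antisense overlaps placed exactly at the 50/51 bp
decision boundary), novel intergenic coding genes, trace-expressed decoys,
and a stage x replicate negative-binomial count matrix with planted fold
changes.

Design notes:

* The genome background is i.i.d. uniform ACGT. Planted content (ORFs,
  splice-site dinucleotides, coding-potential-suppressed lncRNA bodies) is
  overwritten on top of it. lncRNA bodies are drawn from a start-codon-free
  alphabet in transcript orientation so their gate label is controlled; a
  rejection loop re-samples free bases until the label matches the manifest.
* Features are packed left to right with inter-unit gaps larger than the
  500 bp intergenic-distance threshold, so "intergenic" plants are
  intergenic by construction.
* Discrete attributes that must hit their planned proportions (splice-site
  classes, intron lengths) are drawn from a shuffled finite deck rather
  than independently.
* One pseudo-random stream per artifact (sequence, placement, counts),
  split from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from kiwitx import coding_potential as cp
from kiwitx.expression_de import CountMatrix
from kiwitx.transcript_model import (
    ASSEMBLED,
    GeneModel,
    GenomicInterval,
    PREDICTED,
    Transcript,
    reverse_complement,
    write_fasta,
    write_gtf,
)

__all__ = [
    "SimConfig",
    "TruthTranscript",
    "TruthManifest",
    "SimulationError",
    "SimulationResult",
    "simulate_annotation",
    "simulate_counts",
    "simulate_de_counts",
    "write_files",
]


class SimulationError(RuntimeError):
    """Raised when the configured features cannot be packed into the genome."""


@dataclass
class SimConfig:
    seed: int = 0
    seq_name: str = "chr1"
    genome_length: int = 1_000_000

    # annotation plan
    n_plain_genes: int = 22
    n_exon_skipping: int = 30
    n_intron_retention: int = 30
    n_alt_acceptor: int = 30
    n_alt_donor: int = 30
    n_lincrna: int = 50
    n_antisense: int = 18
    antisense_boundary_cases: tuple[int, ...] = (50, 51)
    n_antisense_ncnc_pairs: int = 1
    n_intronic: int = 20
    n_overlapping: int = 18
    n_other_lncrna: int = 15
    n_novel_genes: int = 25
    n_trace: int = 10
    weak_noncoding_fraction: float = 0.3
    lincrna_multi_exon_fraction: float = 0.2
    repeat_fraction: float = 0.4

    # sequence model
    splice_site_mix: tuple[tuple[str, float], ...] = (
        ("GT-AG", 0.90),
        ("GC-AG", 0.06),
        ("AT-AC", 0.02),
        ("other", 0.02),
    )
    intron_length_choices: tuple[tuple[int, float], ...] = ((100, 0.8), (1000, 0.2))
    min_gene_gap: int = 650  # > 500 bp so intergenic plants stay intergenic
    acceptor_shift: int = 30  # bp offset used by alt donor/acceptor isoforms

    # expression model
    stages: tuple[str, ...] = ("20DAP", "120DAP", "127DAP")
    replicates: int = 3
    de_fraction: float = 0.1
    de_fold: float = 4.0
    nb_dispersion: float = 0.1
    baseline_log_mean: float = float(np.log(200.0))
    baseline_log_sd: float = 1.0
    unassigned_fraction: float = 0.1
    as_stage_specific_fraction: float = 0.0


@dataclass
class TruthTranscript:
    transcript_id: str
    gene_id: str
    biotype: str                      # coding | lncRNA | novel_coding | trace
    categories: tuple[str, ...] = ()
    stage_pattern: Optional[tuple[int, ...]] = None  # 1 = expressed at stage
    silenced: bool = False
    antisense_partner_class: Optional[str] = None


@dataclass
class TruthManifest:
    transcripts: dict[str, TruthTranscript] = field(default_factory=dict)
    as_events: list[dict] = field(default_factory=list)
    splice_sites: list[dict] = field(default_factory=list)
    de_genes: dict[str, dict] = field(default_factory=dict)
    repeat_lncrnas: list[str] = field(default_factory=list)
    pair_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "transcripts": {k: asdict(v) for k, v in self.transcripts.items()},
            "as_events": self.as_events,
            "splice_sites": self.splice_sites,
            "de_genes": self.de_genes,
            "repeat_lncrnas": self.repeat_lncrnas,
            "pair_counts": self.pair_counts,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "TruthManifest":
        raw = json.loads(text)
        m = TruthManifest(
            as_events=raw["as_events"],
            splice_sites=raw["splice_sites"],
            de_genes=raw["de_genes"],
            repeat_lncrnas=raw["repeat_lncrnas"],
            pair_counts=raw["pair_counts"],
        )
        for k, v in raw["transcripts"].items():
            v = dict(v)
            v["categories"] = tuple(v["categories"])
            if v["stage_pattern"] is not None:
                v["stage_pattern"] = tuple(v["stage_pattern"])
            m.transcripts[k] = TruthTranscript(**v)
        return m


@dataclass
class SimulationResult:
    config: SimConfig
    genome: dict[str, str]
    predicted: list[GeneModel]
    assembled: list[GeneModel]
    repeats: list[GenomicInterval]
    manifest: TruthManifest

    @property
    def merged(self) -> list[GeneModel]:
        """Predicted and assembled transcripts merged by gene_id."""
        by_gene: dict[str, list[Transcript]] = {}
        order: list[str] = []
        for src in (self.predicted, self.assembled):
            for g in src:
                if g.gene_id not in by_gene:
                    by_gene[g.gene_id] = []
                    order.append(g.gene_id)
                by_gene[g.gene_id].extend(g.transcripts)
        return [GeneModel(gid, by_gene[gid]) for gid in order]


# ---------------------------------------------------------------------------
# helpers

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]
_SITE_DINUCS = {
    "GT-AG": ("GT", "AG"),
    "GC-AG": ("GC", "AG"),
    "AT-AC": ("AT", "AC"),
}
_OTHER_DINUCS = (("CT", "AC"), ("AA", "TT"), ("GG", "CC"))


class _DeckSampler:
    """Draws items in planned proportions using a shuffled finite deck."""

    def __init__(self, choices: Sequence[tuple[object, float]], rng, deck_size: int = 50):
        total = sum(w for _, w in choices)
        counts = [max(1, round(w / total * deck_size)) for _, w in choices]
        self._template = [
            item for (item, _), c in zip(choices, counts) for _ in range(c)
        ]
        self._rng = rng
        self._deck: list = []

    def draw(self):
        if not self._deck:
            self._deck = list(self._template)
            self._rng.shuffle(self._deck)
        return self._deck.pop()


class _SeqView:
    """Read-only string-like view over the mutable genome array."""

    def __init__(self, arr: np.ndarray):
        self._arr = arr

    def __len__(self) -> int:
        return len(self._arr)

    def __getitem__(self, key):
        part = self._arr[key]
        if isinstance(part, np.ndarray):
            return "".join(part.tolist())
        return str(part)


class _GenomeBuilder:
    def __init__(self, config: SimConfig, rng):
        self.config = config
        self.arr = _BASES[rng.integers(0, 4, size=config.genome_length)]
        self.cursor = 1001  # 1-based; leading margin

    def alloc(self, length: int) -> int:
        start = self.cursor
        end = start + length - 1
        if end + self.config.min_gene_gap > self.config.genome_length:
            raise SimulationError(
                f"genome_length={self.config.genome_length} too small for the "
                f"configured features (needed past {end})"
            )
        self.cursor = end + 1 + self.config.min_gene_gap
        return start

    def write(self, start1: int, seq: str) -> None:
        self.arr[start1 - 1 : start1 - 1 + len(seq)] = list(seq)

    def fill(self, start1: int, end1: int, alphabet: str, rng) -> None:
        n = end1 - start1 + 1
        pick = np.array(list(alphabet))
        self.arr[start1 - 1 : end1] = pick[rng.integers(0, len(pick), size=n)]

    def genome_view(self) -> dict[str, _SeqView]:
        return {self.config.seq_name: _SeqView(self.arr)}

    def sequence(self) -> str:
        return "".join(self.arr.tolist())


def _random_orf(rng, length_nt: int) -> str:
    if length_nt % 3 or length_nt < 9:
        raise ValueError("ORF length must be a multiple of 3 and >= 9")
    n_fill = length_nt // 3 - 2
    fill = "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_fill))
    return "ATG" + fill + "TAA"


def _plant_orf(builder: _GenomeBuilder, exon: GenomicInterval, strand: str,
               offset: int, orf: str) -> None:
    """Write an ORF so it reads in transcript orientation at ``offset`` nt
    from the transcript-side start of the exon."""
    if strand == "+":
        builder.write(exon.start + offset, orf)
    else:
        builder.write(exon.end - offset - len(orf) + 1, reverse_complement(orf))


def _plant_splice_site(builder: _GenomeBuilder, intron: GenomicInterval,
                       strand: str, site_class: str, rng) -> None:
    if site_class == "other":
        donor, acceptor = _OTHER_DINUCS[rng.integers(0, len(_OTHER_DINUCS))]
    else:
        donor, acceptor = _SITE_DINUCS[site_class]
    if strand == "+":
        builder.write(intron.start, donor)
        builder.write(intron.end - 1, acceptor)
    else:
        builder.write(intron.start, reverse_complement(acceptor))
        builder.write(intron.end - 1, reverse_complement(donor))


def _noncoding_alphabet(strand: str) -> str:
    # no start codon can arise in transcript orientation:
    # '+' sequences lack G (no ATG); '-' genome slices lack C
    return "ACT" if strand == "+" else "AGT"


def _tx(tid: str, gid: str, exons: list[GenomicInterval], source: str) -> Transcript:
    return Transcript(transcript_id=tid, gene_id=gid, exons=exons, source=source)


# ---------------------------------------------------------------------------
# annotation simulation


class _Simulator:
    def __init__(self, config: SimConfig):
        self.cfg = config
        master = np.random.default_rng(config.seed)
        self.seq_rng, self.place_rng, self.counts_rng = master.spawn(3)
        self.builder = _GenomeBuilder(config, self.seq_rng)
        self.site_deck = _DeckSampler(config.splice_site_mix, self.place_rng)
        self.intron_deck = _DeckSampler(
            [(length, w) for length, w in config.intron_length_choices],
            self.place_rng,
            deck_size=max(
                5, round(1 / min(w for _, w in config.intron_length_choices))
            ),
        )
        self.predicted: list[GeneModel] = []
        self.assembled: list[GeneModel] = []
        self.manifest = TruthManifest()
        self._gene_n = 0
        self._tx_n = 0
        self._site_keys: set[tuple[int, int]] = set()

    # -- id helpers ---------------------------------------------------
    def _gene_id(self, prefix: str) -> str:
        self._gene_n += 1
        return f"{prefix}{self._gene_n:05d}"

    def _tx_id(self, prefix: str) -> str:
        self._tx_n += 1
        return f"{prefix}{self._tx_n:05d}"

    def _record_site(self, intron: GenomicInterval, site_class: str) -> None:
        key = (intron.start, intron.end)
        if key not in self._site_keys:
            self._site_keys.add(key)
            self.manifest.splice_sites.append(
                {
                    "seq_id": intron.seq_id,
                    "start": intron.start,
                    "end": intron.end,
                    "site_class": site_class,
                }
            )

    def _truth(self, tx: Transcript, biotype: str, categories=(), **kw) -> None:
        self.manifest.transcripts[tx.transcript_id] = TruthTranscript(
            tx.transcript_id, tx.gene_id, biotype, tuple(sorted(categories)), **kw
        )

    # -- structural builders -------------------------------------------
    def _exon_chain(self, start: int, exon_lens: Sequence[int],
                    intron_lens: Sequence[int], strand: str) -> tuple[list, list]:
        exons, introns = [], []
        pos = start
        seq = self.cfg.seq_name
        for i, elen in enumerate(exon_lens):
            exons.append(GenomicInterval(seq, pos, pos + elen - 1, strand))
            pos += elen
            if i < len(intron_lens):
                introns.append(GenomicInterval(seq, pos, pos + intron_lens[i] - 1, strand))
                pos += intron_lens[i]
        return exons, introns

    def _plant_gene_sites(self, introns: Sequence[GenomicInterval], strand: str,
                          site_class: Optional[str] = None) -> list[str]:
        classes = []
        for intron in introns:
            cls = site_class or self.site_deck.draw()
            _plant_splice_site(self.builder, intron, strand, cls, self.seq_rng)
            self._record_site(intron, cls)
            classes.append(cls)
        return classes

    def _first_exon(self, exons: list[GenomicInterval], strand: str) -> GenomicInterval:
        return exons[0] if strand == "+" else exons[-1]

    # -- validation ----------------------------------------------------
    def _ensure_noncoding(self, tx: Transcript, want_weak: bool,
                          free_regions: list[tuple[int, int, str]],
                          orf_plan: Optional[tuple[GenomicInterval, int, int]]) -> None:
        """Re-sample free bases until the transcript gates as planned."""
        target = {cp.WEAK_NONCODING} if want_weak else {cp.STRONG_NONCODING}
        genome = self.builder.genome_view()
        for attempt in range(80):
            if attempt > 0:
                for s, e, alphabet in free_regions:
                    self.builder.fill(s, e, alphabet, self.seq_rng)
                if orf_plan is not None:
                    exon, offset, length = orf_plan
                    _plant_orf(self.builder, exon, tx.strand, offset,
                               _random_orf(self.seq_rng, length))
            a = cp.assess_transcript(tx, genome)
            if a.label in target:
                return
        raise SimulationError(
            f"{tx.transcript_id}: could not realize planned noncoding label"
        )

    # -- units ----------------------------------------------------------
    def _rand_strand(self) -> str:
        return "+" if self.place_rng.integers(0, 2) == 0 else "-"

    def _plain_gene(self, with_other_lnc: bool) -> None:
        rng = self.place_rng
        strand = self._rand_strand()
        n_exons = int(rng.integers(2, 4))
        exon_lens = [int(rng.integers(150, 401)) for _ in range(n_exons)]
        intron_lens = [self.intron_deck.draw() for _ in range(n_exons - 1)]
        length = sum(exon_lens) + sum(intron_lens)

        extra = 0
        lnc_len = gap = 0
        if with_other_lnc:
            lnc_len = int(rng.integers(350, 551))
            gap = int(rng.integers(100, 401))
            extra = gap + lnc_len
        start = self.builder.alloc(length + extra)

        exons, introns = self._exon_chain(start, exon_lens, intron_lens, strand)
        self._plant_gene_sites(introns, strand)
        gid = self._gene_id("PG")
        tx = _tx(self._tx_id("PT"), gid, exons, PREDICTED)
        self.predicted.append(GeneModel(gid, [tx]))
        self._truth(tx, "coding")

        if with_other_lnc:
            gene_end = exons[-1].end
            lnc_start = gene_end + gap + 1
            lnc_strand = self._rand_strand()
            lnc_exon = GenomicInterval(self.cfg.seq_name, lnc_start,
                                       lnc_start + lnc_len - 1, lnc_strand)
            self.builder.fill(lnc_exon.start, lnc_exon.end,
                              _noncoding_alphabet(lnc_strand), self.seq_rng)
            lid = self._gene_id("LNCG")
            ltx = _tx(self._tx_id("LNCT"), lid, [lnc_exon], ASSEMBLED)
            self.assembled.append(GeneModel(lid, [ltx]))
            self._ensure_noncoding(
                ltx, want_weak=False,
                free_regions=[(lnc_exon.start, lnc_exon.end,
                               _noncoding_alphabet(lnc_strand))],
                orf_plan=None,
            )
            self._truth(ltx, "lncRNA", ["other"])

    def _as_locus(self, category: str) -> None:
        rng = self.place_rng
        cfg = self.cfg
        strand = self._rand_strand()
        shift = cfg.acceptor_shift
        e1, e2, e3 = 700, 120, 250
        site_class = self.site_deck.draw()
        gid = self._gene_id("PG")
        seq = cfg.seq_name
        # lay out mirrored on '-' so the large ORF-bearing exon (e1) is
        # always the transcript-first exon
        fwd = strand == "+"

        if category == "exon_skipping":
            l1, l2 = self.intron_deck.draw(), self.intron_deck.draw()
            start = self.builder.alloc(e1 + l1 + e2 + l2 + e3)
            lens = [e1, e2, e3] if fwd else [e3, e2, e1]
            exons, introns = self._exon_chain(start, lens, [l1, l2], strand)
            a_exons = exons
            b_exons = [exons[0], exons[2]]
            bridge = GenomicInterval(seq, introns[0].start, introns[1].end, strand)
            planted = introns + [bridge]
            side_long = tuple(sorted(((i.start, i.end) for i in introns)))
            side_short = ((bridge.start, bridge.end),)
        elif category == "intron_retention":
            l1 = self.intron_deck.draw()
            start = self.builder.alloc(e1 + l1 + e3)
            lens = [e1, e3] if fwd else [e3, e1]
            exons, introns = self._exon_chain(start, lens, [l1], strand)
            a_exons = exons
            b_exons = [GenomicInterval(seq, exons[0].start, exons[-1].end, strand)]
            planted = introns
            side_long = ((introns[0].start, introns[0].end),)
            side_short = ()
        else:
            l1 = max(self.intron_deck.draw(), 100)
            start = self.builder.alloc(e1 + l1 + e3 + shift)
            lens = [e1, e3] if fwd else [e3, e1]
            exons, introns = self._exon_chain(start, lens, [l1], strand)
            i0 = introns[0]
            # which genomic boundary moves, given the transcript-level category
            move_right = (category == "alt_acceptor_3p") == (strand == "+")
            if move_right:
                alt = GenomicInterval(seq, i0.start, i0.end + shift, strand)
                b_exons = [exons[0],
                           GenomicInterval(seq, alt.end + 1,
                                           alt.end + exons[1].length, strand)]
            else:
                alt = GenomicInterval(seq, i0.start - shift, i0.end, strand)
                b_exons = [GenomicInterval(seq, exons[0].start,
                                           alt.start - 1, strand),
                           exons[1]]
            a_exons = exons
            planted = [i0, alt]
            side_long = ((i0.start, i0.end),)
            side_short = ((alt.start, alt.end),)

        for intron in planted:
            _plant_splice_site(self.builder, intron, strand, site_class, self.seq_rng)
            self._record_site(intron, site_class)

        orf = _random_orf(self.seq_rng, 600)
        _plant_orf(self.builder, self._first_exon(a_exons, strand), strand, 10, orf)

        tx_a = _tx(self._tx_id("PT"), gid, a_exons, PREDICTED)
        tx_b = _tx(self._tx_id("AT"), gid, b_exons, ASSEMBLED)
        self.predicted.append(GeneModel(gid, [tx_a]))
        self.assembled.append(GeneModel(gid, [tx_b]))

        pattern = None
        if self.place_rng.random() < cfg.as_stage_specific_fraction:
            on = int(self.place_rng.integers(0, len(cfg.stages)))
            pattern = tuple(1 if i == on else 0 for i in range(len(cfg.stages)))
        self._truth(tx_a, "coding")
        self._truth(tx_b, "coding", stage_pattern=pattern)

        side_a, side_b = sorted((side_long, side_short))
        self.manifest.as_events.append(
            {
                "gene_id": gid,
                "category": category,
                "strand": strand,
                "side_a": [list(i) for i in side_a],
                "side_b": [list(i) for i in side_b],
            }
        )

    def _intronic_unit(self) -> None:
        rng = self.place_rng
        strand = self._rand_strand()
        lnc_len = int(rng.integers(350, 501))
        intron_len = lnc_len + 2 * int(rng.integers(60, 200))
        exon_lens = [300, 300]
        start = self.builder.alloc(600 + intron_len)
        exons, introns = self._exon_chain(start, exon_lens, [intron_len], strand)
        self._plant_gene_sites(introns, strand)
        gid = self._gene_id("PG")
        host = _tx(self._tx_id("PT"), gid, exons, PREDICTED)
        self.predicted.append(GeneModel(gid, [host]))
        self._truth(host, "coding")

        margin = (intron_len - lnc_len) // 2
        lnc_start = introns[0].start + margin
        lnc_exon = GenomicInterval(self.cfg.seq_name, lnc_start,
                                   lnc_start + lnc_len - 1, strand)
        self.builder.fill(lnc_exon.start, lnc_exon.end,
                          _noncoding_alphabet(strand), self.seq_rng)
        lid = self._gene_id("LNCG")
        ltx = _tx(self._tx_id("LNCT"), lid, [lnc_exon], ASSEMBLED)
        self.assembled.append(GeneModel(lid, [ltx]))
        self._ensure_noncoding(
            ltx, False,
            [(lnc_exon.start, lnc_exon.end, _noncoding_alphabet(strand))],
            None,
        )
        self._truth(ltx, "lncRNA", ["intronic", "overlapping"])

    def _antisense_unit(self, overlap_bp: int) -> None:
        rng = self.place_rng
        host_strand = self._rand_strand()
        lnc_strand = "-" if host_strand == "+" else "+"
        lnc_len = 400
        exon_lens = [500, 300]
        intron_lens = [self.intron_deck.draw()]
        upstream = lnc_len - overlap_bp
        start = self.builder.alloc(upstream + sum(exon_lens) + sum(intron_lens))
        gene_start = start + upstream
        exons, introns = self._exon_chain(gene_start, exon_lens, intron_lens, host_strand)
        self._plant_gene_sites(introns, host_strand)
        gid = self._gene_id("PG")
        host = _tx(self._tx_id("PT"), gid, exons, PREDICTED)
        self.predicted.append(GeneModel(gid, [host]))
        self._truth(host, "coding")

        lnc_exon = GenomicInterval(self.cfg.seq_name, start,
                                   gene_start + overlap_bp - 1, lnc_strand)
        self.builder.fill(lnc_exon.start, lnc_exon.end,
                          _noncoding_alphabet(lnc_strand), self.seq_rng)
        lid = self._gene_id("LNCG")
        ltx = _tx(self._tx_id("LNCT"), lid, [lnc_exon], ASSEMBLED)
        self.assembled.append(GeneModel(lid, [ltx]))
        self._ensure_noncoding(
            ltx, False,
            [(lnc_exon.start, lnc_exon.end, _noncoding_alphabet(lnc_strand))],
            None,
        )
        cats = ["overlapping"]
        partner_class = None
        if overlap_bp > 50:
            cats.append("antisense")
            partner_class = "coding"
        self._truth(ltx, "lncRNA", cats, antisense_partner_class=partner_class)

    def _overlapping_unit(self) -> None:
        rng = self.place_rng
        strand = self._rand_strand()
        exon_lens = [400, 300]
        intron_lens = [self.intron_deck.draw()]
        lnc_len = 400
        overhang = 200  # bp of the lncRNA outside the gene span
        start = self.builder.alloc(overhang + sum(exon_lens) + sum(intron_lens))
        gene_start = start + overhang
        exons, introns = self._exon_chain(gene_start, exon_lens, intron_lens, strand)
        self._plant_gene_sites(introns, strand)
        gid = self._gene_id("PG")
        host = _tx(self._tx_id("PT"), gid, exons, PREDICTED)
        self.predicted.append(GeneModel(gid, [host]))
        self._truth(host, "coding")

        lnc_exon = GenomicInterval(self.cfg.seq_name, start,
                                   start + lnc_len - 1, strand)  # same strand
        self.builder.fill(lnc_exon.start, lnc_exon.end,
                          _noncoding_alphabet(strand), self.seq_rng)
        lid = self._gene_id("LNCG")
        ltx = _tx(self._tx_id("LNCT"), lid, [lnc_exon], ASSEMBLED)
        self.assembled.append(GeneModel(lid, [ltx]))
        self._ensure_noncoding(
            ltx, False,
            [(lnc_exon.start, lnc_exon.end, _noncoding_alphabet(strand))],
            None,
        )
        self._truth(ltx, "lncRNA", ["overlapping"])

    def _lincrna_unit(self) -> None:
        rng = self.place_rng
        strand = self._rand_strand()
        want_weak = rng.random() < self.cfg.weak_noncoding_fraction
        multi = rng.random() < self.cfg.lincrna_multi_exon_fraction
        if multi:
            exon_lens = [int(rng.integers(200, 401)), int(rng.integers(150, 301))]
            intron_lens = [self.intron_deck.draw()]
        else:
            exon_lens = [int(rng.integers(400, 901))]
            intron_lens = []
        start = self.builder.alloc(sum(exon_lens) + sum(intron_lens))
        exons, introns = self._exon_chain(start, exon_lens, intron_lens, strand)
        free = [(e.start, e.end, _noncoding_alphabet(strand)) for e in exons]
        for s, e, alphabet in free:
            self.builder.fill(s, e, alphabet, self.seq_rng)
        self._plant_gene_sites(introns, strand)

        orf_plan = None
        if want_weak:
            orf_len = 150
            first = self._first_exon(exons, strand)
            orf_plan = (first, 20, orf_len)
            _plant_orf(self.builder, first, strand, 20,
                       _random_orf(self.seq_rng, orf_len))

        lid = self._gene_id("LNCG")
        ltx = _tx(self._tx_id("LNCT"), lid, exons, ASSEMBLED)
        self.assembled.append(GeneModel(lid, [ltx]))
        self._ensure_noncoding(ltx, want_weak, free, orf_plan)
        self._truth(ltx, "lncRNA", ["lincRNA"])

    def _ncnc_pair_unit(self) -> None:
        rng = self.place_rng
        len_a = len_b = 500
        overlap = 100
        start = self.builder.alloc(len_a + len_b - overlap)
        seq = self.cfg.seq_name
        ex_a = GenomicInterval(seq, start, start + len_a - 1, "+")
        ex_b = GenomicInterval(seq, ex_a.end - overlap + 1,
                               ex_a.end - overlap + len_b, "-")
        # overlap bases must suppress starts on both strands -> {A,T}
        self.builder.fill(ex_a.start, ex_b.start - 1, "ACT", self.seq_rng)
        self.builder.fill(ex_b.start, ex_a.end, "AT", self.seq_rng)
        self.builder.fill(ex_a.end + 1, ex_b.end, "AGT", self.seq_rng)
        txs = []
        for exon, other in ((ex_a, ex_b), (ex_b, ex_a)):
            lid = self._gene_id("LNCG")
            ltx = _tx(self._tx_id("LNCT"), lid, [exon], ASSEMBLED)
            self.assembled.append(GeneModel(lid, [ltx]))
            txs.append(ltx)
        free = [
            (ex_a.start, ex_b.start - 1, "ACT"),
            (ex_b.start, ex_a.end, "AT"),
            (ex_a.end + 1, ex_b.end, "AGT"),
        ]
        for ltx in txs:
            self._ensure_noncoding(ltx, False, free, None)
            self._truth(ltx, "lncRNA", ["lincRNA", "antisense"],
                        antisense_partner_class="noncoding")

    def _novel_gene_unit(self) -> None:
        rng = self.place_rng
        strand = self._rand_strand()
        length = 700
        start = self.builder.alloc(length)
        exon = GenomicInterval(self.cfg.seq_name, start, start + length - 1, strand)
        _plant_orf(self.builder, exon, strand, 20, _random_orf(self.seq_rng, 450))
        gid = self._gene_id("NVG")
        tx = _tx(self._tx_id("NVT"), gid, [exon], ASSEMBLED)
        self.assembled.append(GeneModel(gid, [tx]))
        self._truth(tx, "novel_coding")

    def _trace_unit(self) -> None:
        strand = self._rand_strand()
        length = 500
        start = self.builder.alloc(length)
        exon = GenomicInterval(self.cfg.seq_name, start, start + length - 1, strand)
        self.builder.fill(exon.start, exon.end, _noncoding_alphabet(strand), self.seq_rng)
        gid = self._gene_id("TRG")
        tx = _tx(self._tx_id("TRT"), gid, [exon], ASSEMBLED)
        self.assembled.append(GeneModel(gid, [tx]))
        self._truth(tx, "trace", silenced=True)

    # -- orchestration ---------------------------------------------------
    def run(self) -> SimulationResult:
        cfg = self.cfg
        for category, n in (
            ("exon_skipping", cfg.n_exon_skipping),
            ("intron_retention", cfg.n_intron_retention),
            ("alt_acceptor_3p", cfg.n_alt_acceptor),
            ("alt_donor_5p", cfg.n_alt_donor),
        ):
            for _ in range(n):
                self._as_locus(category)
        for _ in range(cfg.n_intronic):
            self._intronic_unit()
        for _ in range(cfg.n_antisense):
            self._antisense_unit(int(self.place_rng.integers(60, 201)))
        for overlap in cfg.antisense_boundary_cases:
            self._antisense_unit(overlap)
        for _ in range(cfg.n_overlapping):
            self._overlapping_unit()
        n_anchored = min(cfg.n_other_lncrna, cfg.n_plain_genes)
        if n_anchored < cfg.n_other_lncrna:
            raise SimulationError(
                "n_other_lncrna cannot exceed n_plain_genes (each needs a "
                "nearby gene anchor)"
            )
        for i in range(cfg.n_plain_genes):
            self._plain_gene(with_other_lnc=i < n_anchored)
        for _ in range(cfg.n_lincrna):
            self._lincrna_unit()
        for _ in range(cfg.n_antisense_ncnc_pairs):
            self._ncnc_pair_unit()
        for _ in range(cfg.n_novel_genes):
            self._novel_gene_unit()
        for _ in range(cfg.n_trace):
            self._trace_unit()

        self.manifest.pair_counts = {
            "noncoding_coding": sum(
                1 for t in self.manifest.transcripts.values()
                if t.antisense_partner_class == "coding"
            ),
            "noncoding_noncoding": sum(
                1 for t in self.manifest.transcripts.values()
                if t.antisense_partner_class == "noncoding"
            ),
        }

        repeats = self._plant_repeats()
        return SimulationResult(
            config=cfg,
            genome={cfg.seq_name: self.builder.sequence()},
            predicted=self.predicted,
            assembled=self.assembled,
            repeats=repeats,
            manifest=self.manifest,
        )

    def _plant_repeats(self) -> list[GenomicInterval]:
        repeats: list[GenomicInterval] = []
        lnc_ids = [
            t.transcript_id for t in self.manifest.transcripts.values()
            if t.biotype == "lncRNA"
        ]
        by_id = {
            t.transcript_id: t
            for g in self.assembled for t in g.transcripts
        }
        n_with = round(self.cfg.repeat_fraction * len(lnc_ids))
        chosen = list(self.place_rng.choice(lnc_ids, size=n_with, replace=False)) \
            if n_with else []
        for tid in sorted(chosen):
            exon = by_id[tid].exons[0]
            mid = (exon.start + exon.end) // 2
            repeats.append(GenomicInterval(exon.seq_id, mid, mid + 29, "."))
            self.manifest.repeat_lncrnas.append(tid)
        return sorted(repeats, key=lambda r: r.start)


def simulate_annotation(config: SimConfig) -> SimulationResult:
    """Generate genome, predicted + assembled annotation, repeats, and the
    ground-truth manifest. Deterministic under (seed, config)."""
    return _Simulator(config).run()


# ---------------------------------------------------------------------------
# count simulation


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    config: SimConfig,
    manifest: TruthManifest,
    result: SimulationResult,
) -> CountMatrix:
    """Negative-binomial counts per (transcript, stage, replicate).

    Stage means are a lognormal baseline times the planted fold pattern of
    the transcript's gene (DE genes) and the planted stage on/off pattern;
    silenced transcripts get zero counts everywhere.
    """
    rng = np.random.default_rng([config.seed, 1_000_003])
    tids, gids = [], []
    for g in result.merged:
        for t in g.transcripts:
            tids.append(t.transcript_id)
            gids.append(t.gene_id)

    coding_genes = sorted(
        {
            t.gene_id for t in manifest.transcripts.values()
            if t.biotype == "coding"
        }
    )
    n_de = round(config.de_fraction * len(coding_genes))
    de_genes = sorted(rng.choice(coding_genes, size=n_de, replace=False)) if n_de else []
    if not manifest.de_genes:
        for g in de_genes:
            stage_idx = int(rng.integers(0, len(config.stages)))
            manifest.de_genes[g] = {"fold": config.de_fold, "stage": stage_idx}

    n_stage, n_rep = len(config.stages), config.replicates
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                             size=len(tids))
    means = np.repeat(baseline[:, None], n_stage, axis=1)
    for i, (tid, gid) in enumerate(zip(tids, gids)):
        truth = manifest.transcripts[tid]
        if truth.silenced:
            means[i] = 0.0
            continue
        de = manifest.de_genes.get(gid)
        if de is not None:
            means[i, de["stage"]] *= de["fold"]
        if truth.stage_pattern is not None:
            means[i] *= np.asarray(truth.stage_pattern, dtype=float)

    cells = np.repeat(means, n_rep, axis=1)
    counts = _nb_draw(rng, cells, config.nb_dispersion)
    columns = pd.MultiIndex.from_tuples(
        [(s, f"rep{r + 1}") for s in config.stages for r in range(n_rep)],
        names=["stage", "replicate"],
    )
    df = pd.DataFrame(counts, index=tids, columns=columns)
    totals = (df.sum(axis=0) * (1.0 + config.unassigned_fraction)).round().astype(int)
    totals[totals == 0] = 1
    return CountMatrix(counts=df, totals=totals)


def simulate_de_counts(
    n_genes: int,
    config: SimConfig,
    seed: Optional[int] = None,
) -> tuple[CountMatrix, dict[str, float], pd.DataFrame]:
    """Stand-alone gene-level count study for DE parameter recovery.

    Returns (counts, gene lengths, truth table with is_de / fold / stage).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    lengths = {g: float(rng.integers(500, 5001)) for g in genes}
    n_de = round(config.de_fraction * n_genes)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[rng.choice(n_genes, size=n_de, replace=False)] = True
    stage_idx = rng.integers(0, len(config.stages), size=n_genes)

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                             size=n_genes).clip(5.0, None)
    n_stage, n_rep = len(config.stages), config.replicates
    means = np.repeat(baseline[:, None], n_stage, axis=1)
    for i in np.flatnonzero(is_de):
        means[i, stage_idx[i]] *= config.de_fold

    cells = np.repeat(means, n_rep, axis=1)
    counts = _nb_draw(rng, cells, config.nb_dispersion)
    columns = pd.MultiIndex.from_tuples(
        [(s, f"rep{r + 1}") for s in config.stages for r in range(n_rep)],
        names=["stage", "replicate"],
    )
    df = pd.DataFrame(counts, index=genes, columns=columns)
    totals = (df.sum(axis=0) * (1.0 + config.unassigned_fraction)).round().astype(int)
    truth = pd.DataFrame(
        {"is_de": is_de, "fold": np.where(is_de, config.de_fold, 1.0),
         "stage": [config.stages[i] for i in stage_idx]},
        index=genes,
    )
    return CountMatrix(counts=df, totals=totals), lengths, truth


# ---------------------------------------------------------------------------
# file output


def write_files(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA / GTFs / BED / manifest JSON; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "predicted": out / "predicted.gtf",
        "assembled": out / "assembled.gtf",
        "repeats": out / "repeats.bed",
        "manifest": out / "manifest.json",
    }
    write_fasta(result.genome, str(paths["genome"]))
    write_gtf(result.predicted, str(paths["predicted"]), source="sim_predicted")
    write_gtf(result.assembled, str(paths["assembled"]), source="sim_assembled")
    with open(paths["repeats"], "w") as fh:
        for r in result.repeats:
            fh.write(f"{r.seq_id}\t{r.start - 1}\t{r.end}\trepeat\t0\t{r.strand}\n")
    paths["manifest"].write_text(result.manifest.to_json())
    return paths
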