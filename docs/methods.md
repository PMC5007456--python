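# Methods

This document describes the analytical model implemented by `kiwitx`,
the parameter defaults, and the reasoning behind the places where a
choice had to be made.

## Coordinate and transcript model

All genomic coordinates are 1-based and inclusive, matching GTF. A
transcript is a non-overlapping, non-adjacent exon chain on one sequence
and strand; introns are exactly the gaps between consecutive exons, so
exon lengths plus intron lengths always equal the span length. Adjacent
exons (gap of zero) are rejected as an invalid chain rather than merged
silently: a zero-length intron is not a splicing event, and accepting it
would corrupt downstream intron statistics.

Interval overlap is counted in shared bases (inclusive on both ends);
the distance between non-overlapping intervals is the number of bases
strictly between them, 0 for touching or overlapping intervals, and
infinite across different sequences.

## Coding potential and gates

The ORF finder scans the three sense frames of the spliced transcript
sequence for the longest ATG-initiated, stop-terminated ORF (length
includes the stop codon); ties break to the smaller start offset, and
when no complete ORF exists the longest ATG-to-end open stretch is
reported as incomplete. Transcripts of unknown strand are not scanned.

The default coding score is a transparent length-based surrogate,

```
score = (orf_nt / 300 − 1) + (orf_nt / transcript_nt − 0.5)
        + 0.25 · (1 if complete else −1)
```

so score 0 sits near the classic 300-nt ORF boundary and the score grows
with both absolute and relative ORF length. A user-supplied score table
(e.g., from a dedicated coding-potential tool) overrides the surrogate
verbatim per transcript.

Gates:

- **lncRNA**: assembled transcripts only; shorter than 200 nt →
  `too_short`; score < 0 *and* ORF < 300 nt → noncoding, split into
  `weak_noncoding` (−1 ≤ score < 0; −1 itself is weak) and
  `strong_noncoding` (score < −1); everything else → `coding`. Predicted
  models are never gated (`predicted_model`).
- **Novel gene**: assembled, more than 500 bp from every predicted gene
  span, ORF strictly greater than 300 nt, score strictly positive. Novel
  transcripts are grouped into genes by same-strand span overlap.

## lncRNA anatomy

Classification is multi-label; each gated lncRNA receives every category
whose rule it satisfies:

- **lincRNA**: more than 500 bp from the nearest predicted gene span.
- **overlapping**: at least 1 bp of span overlap with a coding gene span
  (predicted genes and novel coding genes), excluding the lncRNA's own
  gene id.
- **antisense**: exonic overlap strictly greater than 50 bp with an
  opposite-strand transcript; partners may be coding or other gated
  lncRNAs, which is what produces noncoding–noncoding sense–antisense
  pairs.
- **intronic**: span contained entirely within a single intron of a
  coding transcript (strand-independent).
- **other**: none of the above.

Transcripts of unknown strand skip the stranded rules with a warning.
For single-label reporting the precedence is antisense > intronic >
overlapping > lincRNA > other. Pair detection emits one intronic pair
per (lncRNA, host transcript) and one antisense pair per qualifying
partner. Repeat-overlap annotation flags lncRNAs whose *exons* intersect
a supplied repeat interval by at least 1 bp; a repeat inside an lncRNA's
intron does not count.

## Alternative-splicing events

For every isoform pair at a locus, both intron chains are restricted to
the genomic window the two transcripts share, then aligned on shared
splice sites (a site is a boundary position plus its side, intron start
or intron end). Each maximal run of non-shared sites between two
consecutive shared sites (or a chain end) emits one event whose two
sides are the intron sub-chains involved; when one side has no intron
boundary inside the run but carries a single intron whose boundaries are
exactly the two flanking shared sites, that bridging intron is the side
(this is the exon-skipping configuration). Signatures are stored with
their sides in canonical order, and identical signatures from different
isoform pairs are merged so event counts reflect unique structures.

Classification is a pure function of the signature: one intron per side
sharing the genomic-left boundary is an alternative acceptor on `+` and
an alternative donor on `−` (on the minus strand the genomic right end
of an intron is the donor); sharing the genomic-right boundary is the
mirror case; one intron versus none is intron retention; two introns
versus one bridging both is exon skipping; everything else is `other`.

A consequence of the strand correction worth stating explicitly: keeping
coordinates fixed and relabeling the strand swaps the two alternative-
site categories while preserving intron retention and exon skipping,
whereas a true coordinate mirror plus strand flip preserves all
categories. Both invariants are tested.

Splice sites are classed per unique genomic intron from the donor and
acceptor dinucleotides read in transcript orientation (on `−`, the
genome slice is reverse-complemented first): GT-AG, GC-AG, AT-AC, or
other. Introns shorter than 4 bp are classed `other` with a warning.
Per-stage event counting marks an event present at a stage when both of
its sides have at least one supporting isoform with FPKM at or above the
stage-expression threshold (default 0.1).

## Expression and differential expression

FPKM = count × 10⁹ / (length × total mapped fragments). Replicate QC
computes Pearson correlations on log₂(FPKM + 1) within each stage and
excludes a replicate only when it falls strictly below the threshold
(default 0.85) against *every* other replicate of its stage; single-
replicate stages are skipped with a warning. Transcripts below the trace
threshold (FPKM < 0.01) at every stage are dropped before the coding
gates and AS analysis.

The DE gate is: max/min stage-mean FPKM ratio ≥ 2 and BH-adjusted
P < 0.01. A zero minimum is floored at 0.01 and flagged; an all-zero
gene is undefined (NaN) and never called. P-values come from a one-way
fixed-effects F-test on log₂(FPKM + 1).

**Why the default F-test pools its variance across genes.** With three
stages and two or three replicates, a per-gene residual variance has
only 3–6 degrees of freedom. A noncentral-F power calculation at these
settings (4-fold change, negative-binomial dispersion 0.1, BH-effective
per-test level ~10⁻³) puts per-gene power near 0.35, and simulation
confirms sensitivity around 0.13 — the per-gene test cannot usefully
detect even strong planted changes at this design size. Pooling the
residual variance across all genes (the limiting case of the variance
moderation used by standard RNA-seq packages, under a homoscedastic
log-scale noise model) raises sensitivity to ~0.98 at an observed FDR of
~0.01 in the same simulation. The pooled test is therefore the default
(`variance="pooled"`); the textbook per-gene ANOVA remains available as
`variance="per_gene"`, and externally computed p-values can be supplied
instead of either. `anova_f` itself is the exact textbook per-gene test
and is cross-checked against `scipy.stats.f_oneway`.

Benjamini–Hochberg adjustment uses `statsmodels`' step-up implementation
and is tested against a quadratic-time reference.

## Simulator

The simulator emits a genome FASTA, predicted and assembled GTFs, a
repeats BED, a counts/totals TSV pair, and a JSON manifest holding the
planted truth for every transcript, AS event, splice site, and DE gene.

Design choices:

- The genome background is i.i.d. uniform ACGT; planted content is
  overwritten on top of it.
- Features are packed left to right with inter-unit gaps larger than the
  500-bp intergenic threshold (default 650 bp), so intergenic plants are
  intergenic by construction.
- lncRNA bodies are drawn from start-codon-free alphabets in transcript
  orientation (`ACT` for `+` bodies — no G means no ATG; `AGT` genome
  slices for `−` bodies — no C means no ATG after reverse complement;
  `AT` where two noncoding transcripts overlap on opposite strands). A
  rejection loop then re-samples the free bases until the package's own
  gate reproduces the planned label; the ORF finder used for this check
  is independently oracle-tested, which breaks the circularity.
- Discrete attributes with planned proportions (splice-site classes,
  intron lengths) are drawn from shuffled finite decks rather than
  independently, so the realized mix matches the plan exactly.
- On `−`-strand AS loci the exon-length layout is mirrored so the large
  ORF-bearing exon is always transcript-first; alternative-boundary
  shifts never cut into the planted ORF.
- Counts are negative-binomial (dispersion 0, i.e., Poisson, is
  supported) around a lognormal baseline, with planted fold changes on a
  chosen stage for DE genes, on/off patterns for stage-specific
  isoforms, and all-zero rows for trace decoys. Column totals include a
  configurable unassigned-fragment fraction.
- Three pseudo-random streams (sequence, placement, counts) are spawned
  from the master seed; everything is deterministic under
  `(seed, config)`.

The default configuration plants 200 genes, 125 lncRNAs (including
antisense overlaps at exactly 50 and 51 bp, one noncoding–noncoding
antisense pair, and a 30% weak-noncoding fraction), 120 AS events (30
per category), a 90/6/2/2% splice-site mix, 25 novel genes, and 10 trace
decoys in a 1-Mb genome.

## Reporting

Percentages in all rendered tables use round-half-away-from-zero at one
decimal (via `decimal.Decimal`), which reproduces the rounding style of
the published tables this pipeline emulates (e.g., 98.3 / 1.1 / 0.2 /
0.4 for the splice-site classes). Tables are written as both TSV and
JSON, and each run writes `resolved_config.json` with every threshold so
the outputs are reproducible from the run directory alone.

## Scope and limitations

- The coding-score surrogate is deliberately simple; for real data,
  supply scores from a dedicated coding-potential tool via the override
  table.
- Event enumeration is pairwise with signature deduplication, not a full
  splice-graph decomposition; complex regions that fit no template are
  reported as `other` rather than decomposed further.
- The DE model assumes homoscedastic log-scale noise when pooling
  variance; datasets with strong mean–variance trends should supply
  external p-values from a dedicated DE package.
- The simulator validates planted labels with the package's own gates;
  it guarantees consistency with its manifest, not biological realism.
- Replicate QC never excludes when a stage has a single replicate; it
  warns instead.
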