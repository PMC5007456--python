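"""End-to-end orchestration: parse -> coding gates -> anatomy -> AS ->
expression/DE -> reports.

Each stage logs its input/output counts; any stage failure is re-raised
with the stage name attached. Every run writes the resolved configuration
next to the outputs so all reported numbers are reproducible from the run
directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from kiwitx import as_events as ae
from kiwitx import coding_potential as cp
from kiwitx import expression_de as ed
from kiwitx import lncrna_anatomy as la
from kiwitx import report as rp
from kiwitx.transcript_model import (
    ASSEMBLED,
    GeneModel,
    PREDICTED,
    Transcript,
    load_genome,
    parse_gtf,
    read_bed,
    summarize_intron_lengths,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "RunResult", "run_pipeline",
           "read_counts", "write_counts", "merge_annotations"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class RunConfig:
    # inputs
    genome_fasta: str = ""
    predicted_gtf: str = ""
    assembled_gtf: str = ""
    repeats_bed: Optional[str] = None
    counts_tsv: Optional[str] = None
    totals_tsv: Optional[str] = None
    score_table: Optional[str] = None
    # thresholds (defaults follow the published analysis)
    min_lncrna_length: int = 200
    orf_gate_nt: int = 300
    intergenic_distance: int = 500
    antisense_overlap: int = 50
    ratio_threshold: float = 2.0
    p_threshold: float = 0.01
    qc_threshold: float = 0.85
    trace_eps: float = 0.01
    stage_expression_eps: float = 0.1
    de_variance: str = "pooled"
    # output
    outdir: str = "kiwitx_run"
    seed: int = 0

    def __post_init__(self) -> None:
        fixed = {
            "min_lncrna_length": cp.MIN_LNCRNA_LENGTH,
            "orf_gate_nt": cp.ORF_GATE_NT,
            "intergenic_distance": cp.NOVEL_GENE_MIN_DISTANCE,
            "antisense_overlap": la.ANTISENSE_MIN_OVERLAP,
        }
        for name, expected in fixed.items():
            if getattr(self, name) != expected:
                raise ValueError(
                    f"{name} is fixed at {expected} in this implementation"
                )

    @staticmethod
    def from_json(path: str) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        valid = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**data)


@dataclass
class RunResult:
    outdir: Path
    lncrna_records: list = field(default_factory=list)
    novel_groups: list = field(default_factory=list)
    events: list = field(default_factory=list)
    site_tallies: dict = field(default_factory=dict)
    de: Optional[ed.DEResult] = None
    tables: dict = field(default_factory=dict)


def write_counts(counts: ed.CountMatrix, counts_path: str, totals_path: str) -> None:
    """Counts TSV with 'stage:replicate' columns plus a totals TSV."""
    flat = counts.counts.copy()
    flat.columns = [f"{s}:{r}" for s, r in counts.counts.columns]
    flat.index.name = "transcript_id"
    flat.to_csv(counts_path, sep="\t")
    totals = counts.totals.copy()
    totals.index = [f"{s}:{r}" for s, r in totals.index]
    totals.rename("total").rename_axis("column").to_csv(totals_path, sep="\t")


def read_counts(counts_path: str, totals_path: Optional[str] = None) -> ed.CountMatrix:
    flat = pd.read_csv(counts_path, sep="\t", index_col=0)
    tuples = []
    for col in flat.columns:
        if ":" not in col:
            raise ValueError(f"{counts_path}: column {col!r} is not 'stage:replicate'")
        s, r = col.split(":", 1)
        tuples.append((s, r))
    flat.columns = pd.MultiIndex.from_tuples(tuples, names=["stage", "replicate"])
    if totals_path is not None:
        t = pd.read_csv(totals_path, sep="\t", index_col=0)["total"]
        t.index = flat.columns
        totals = t
    else:
        logger.warning("no totals file; using column sums as totals")
        totals = flat.sum(axis=0)
    return ed.CountMatrix(counts=flat, totals=totals)


def merge_annotations(predicted: list[GeneModel], assembled: list[GeneModel]) -> list[GeneModel]:
    """Union of both annotations, merging transcripts that share gene_id."""
    by_gene: dict[str, list[Transcript]] = {}
    order: list[str] = []
    for src in (predicted, assembled):
        for g in src:
            if g.gene_id not in by_gene:
                by_gene[g.gene_id] = []
                order.append(g.gene_id)
            by_gene[g.gene_id].extend(g.transcripts)
    return [GeneModel(gid, by_gene[gid]) for gid in order]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kw):
            try:
                return fn(*args, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True)
    )
    result = RunResult(outdir=outdir)

    # -- stage: parse ---------------------------------------------------
    @_stage("parse")
    def _parse():
        genome = load_genome(config.genome_fasta)
        predicted = parse_gtf(config.predicted_gtf, source_tag=PREDICTED)
        assembled = parse_gtf(config.assembled_gtf, source_tag=ASSEMBLED)
        repeats = read_bed(config.repeats_bed) if config.repeats_bed else None
        logger.info("parse: %d predicted genes, %d assembled models",
                    len(predicted), len(assembled))
        return genome, predicted, assembled, repeats

    genome, predicted, assembled, repeats = _parse()
    if not assembled:
        logger.warning("assembled annotation is empty; reports will be empty")
    merged = merge_annotations(predicted, assembled)
    all_txs = [t for g in merged for t in g.transcripts]
    assembled_txs = [t for t in all_txs if t.source == ASSEMBLED]

    # -- stage: expression ------------------------------------------------
    @_stage("expression")
    def _expression():
        if config.counts_tsv is None:
            logger.warning("no counts supplied; expression stages skipped")
            return None, None, set()
        counts = read_counts(config.counts_tsv, config.totals_tsv)
        lengths = {t.transcript_id: float(t.length) for t in all_txs}
        fpkm = ed.compute_fpkm(counts, lengths)
        qc = ed.replicate_qc(fpkm, config.qc_threshold)
        if qc.excluded:
            drop = [c for c in fpkm.columns if (c[0], c[1]) in set(qc.excluded)]
            logger.info("expression: excluding replicates %s", qc.excluded)
            fpkm = fpkm.drop(columns=drop)
        means = ed.stage_means(fpkm)
        kept, dropped = ed.filter_trace(means, config.trace_eps)
        logger.info("expression: %d transcripts kept, %d trace-filtered",
                    len(kept), len(dropped))
        return counts, means, set(dropped)

    counts, stage_fpkm, trace_ids = _expression()

    # -- stage: coding gates ------------------------------------------------
    @_stage("coding_gates")
    def _gates():
        override = cp.read_score_table(config.score_table) if config.score_table else None
        candidates = [t for t in assembled_txs if t.transcript_id not in trace_ids]
        assessments = {}
        lnc, novel = [], []
        for t in candidates:
            a = cp.assess_transcript(t, genome, override)
            assessments[t.transcript_id] = a
            t.biotype = a.label
            if a.label in (cp.WEAK_NONCODING, cp.STRONG_NONCODING):
                lnc.append(t)
            elif cp.gate_novel_gene(t, a, predicted):
                t.biotype = "novel_coding"
                novel.append(t)
        groups = cp.group_novel_genes(novel)
        logger.info("coding_gates: %d candidates -> %d lncRNAs, %d novel "
                    "transcripts in %d novel genes",
                    len(candidates), len(lnc), len(novel), len(groups))
        return assessments, lnc, novel, groups

    assessments, lnc_txs, novel_txs, novel_groups = _gates()
    result.novel_groups = novel_groups

    # -- stage: anatomy ----------------------------------------------------
    @_stage("anatomy")
    def _anatomy():
        coding_txs = [t for g in predicted for t in g.transcripts] + novel_txs
        records = la.classify_all(lnc_txs, predicted, coding_txs)
        pairs = la.detect_pairs(records)
        la.annotate_repeat_overlap(records, lnc_txs, repeats)
        summary = la.summarize_anatomy(records, lnc_txs)
        logger.info("anatomy: %s", summary.counts)
        return records, pairs, summary

    lnc_records, pairs, anatomy_summary = _anatomy()
    result.lncrna_records = lnc_records

    # -- stage: alternative splicing ----------------------------------------
    @_stage("as_events")
    def _as():
        active = [
            GeneModel(g.gene_id,
                      [t for t in g.transcripts if t.transcript_id not in trace_ids])
            for g in merged
            if sum(t.transcript_id not in trace_ids for t in g.transcripts) >= 1
        ]
        events = ae.enumerate_events_all(active)
        chains = ae.extract_splice_chains(
            [t for g in active for t in g.transcripts]
        )
        sites = ae.classify_splice_sites(chains, genome)
        tallies = ae.tally_site_classes(sites)
        logger.info("as_events: %d events, site tallies %s", len(events), tallies)
        stage_table = None
        if stage_fpkm is not None:
            per_stage = {
                s: stage_fpkm[s].to_dict() for s in stage_fpkm.columns
            }
            stage_table = ae.count_events_by_stage(
                events, per_stage, list(stage_fpkm.columns),
                threshold=config.stage_expression_eps,
            )
        return events, tallies, stage_table

    events, site_tallies, stage_events = _as()
    result.events = events
    result.site_tallies = site_tallies

    # -- stage: differential expression ---------------------------------------
    @_stage("differential_expression")
    def _de():
        if counts is None:
            return None
        gene_of = {t.transcript_id: t.gene_id for t in all_txs}
        gene_counts = counts.counts.groupby(
            counts.counts.index.map(gene_of)
        ).sum()
        gm = ed.CountMatrix(counts=gene_counts, totals=counts.totals)
        gene_len = {
            g.gene_id: float(max(t.length for t in g.transcripts)) for g in merged
        }
        de = ed.run_de(
            gm, gene_len,
            ratio_threshold=config.ratio_threshold,
            p_threshold=config.p_threshold,
            qc_threshold=config.qc_threshold,
            variance=config.de_variance,
        )
        logger.info("differential_expression: %d/%d genes called DE",
                    int(de.table["is_de"].sum()), len(de.table))
        return de

    de = _de()
    result.de = de

    # -- stage: report ----------------------------------------------------
    @_stage("report")
    def _report():
        from collections import Counter
        tables = {
            "lncrna_summary": rp.render_lncrna_summary(
                anatomy_summary, len(novel_txs), len(novel_groups)
            ),
            "exon_distribution": rp.render_exon_table(anatomy_summary),
            "as_events": rp.render_as_table(
                Counter(e.category for e in events), site_tallies
            ),
        }
        if stage_events is not None:
            tables["as_by_stage"] = rp.render_stage_table(
                stage_events, list(stage_events)
            )
        if de is not None:
            tables["de_genes"] = rp.render_de_table(de.table)
        intron_summary = summarize_intron_lengths(
            t for t in all_txs if t.transcript_id not in trace_ids
        )
        tables["intron_lengths"] = pd.DataFrame(
            intron_summary.histogram, columns=["bin", "count"]
        )
        pair_rows = [
            (p.lncrna_id, p.partner_id, p.pair_type, p.partner_class)
            for p in pairs
        ]
        tables["pairs"] = pd.DataFrame(
            pair_rows, columns=["lncrna_id", "partner_id", "pair_type", "partner_class"]
        )
        rp.write_tables(tables, outdir)
        return tables

    result.tables = _report()
    logger.info("pipeline complete; outputs in %s", outdir)
    return result
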