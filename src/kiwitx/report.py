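"""Rendering of the summary tables (study-style shapes) as DataFrames,
TSV, and JSON.

Percentages are rendered with round-half-away-from-zero at one decimal,
matching the style of the published tables this pipeline emulates.
"""

from __future__ import annotations

import json
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from kiwitx.as_events import EVENT_CATEGORIES, SITE_CLASSES
from kiwitx.lncrna_anatomy import AnatomySummary, PRECEDENCE

__all__ = [
    "percent",
    "render_lncrna_summary",
    "render_exon_table",
    "render_as_table",
    "render_stage_table",
    "render_de_table",
    "write_tables",
]


def percent(n: float, total: float, decimals: int = 1) -> float:
    """Share of ``total`` in percent, round-half-away-from-zero."""
    if total == 0:
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    value = Decimal(100) * Decimal(str(n)) / Decimal(str(total))
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def render_lncrna_summary(
    summary: AnatomySummary,
    n_novel_transcripts: int = 0,
    n_novel_genes: int = 0,
) -> pd.DataFrame:
    """lncRNA / novel-gene overview (one row per category plus totals)."""
    rows = [("lncRNAs (total)", summary.total)]
    rows += [(cat, summary.counts.get(cat, 0)) for cat in PRECEDENCE]
    rows += [
        ("novel transcripts", n_novel_transcripts),
        ("novel genes", n_novel_genes),
    ]
    return pd.DataFrame(rows, columns=["category", "count"])


def render_exon_table(summary: AnatomySummary) -> pd.DataFrame:
    """Exon-number distribution per category; column sums equal the
    category totals of the overview table by construction."""
    cols = list(PRECEDENCE) + ["all"]
    max_exons = max(
        (n for hist in summary.exon_histogram.values() for n in hist),
        default=1,
    )
    data = {
        col: [summary.exon_histogram.get(col, {}).get(n, 0)
              for n in range(1, max_exons + 1)]
        for col in cols
    }
    table = pd.DataFrame(data, index=pd.Index(range(1, max_exons + 1), name="exons"))
    table.loc["total"] = table.sum()
    return table


def render_as_table(
    event_counts: Mapping[str, int],
    site_tallies: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """AS category counts (and optionally splice-site class tallies) with
    one-decimal percentage columns."""
    rows = []
    ev_total = sum(event_counts.get(c, 0) for c in EVENT_CATEGORIES)
    for cat in EVENT_CATEGORIES:
        n = event_counts.get(cat, 0)
        rows.append(("event", cat, n, percent(n, ev_total)))
    rows.append(("event", "total", ev_total, percent(ev_total, ev_total)))
    if site_tallies is not None:
        site_total = sum(site_tallies.get(c, 0) for c in SITE_CLASSES)
        for cls in SITE_CLASSES:
            n = site_tallies.get(cls, 0)
            rows.append(("splice_site", cls, n, percent(n, site_total)))
        rows.append(("splice_site", "total", site_total, percent(site_total, site_total)))
    return pd.DataFrame(rows, columns=["kind", "category", "count", "percent"])


def render_stage_table(
    stage_counts: Mapping[str, Mapping[str, int]],
    stages: Sequence[str],
) -> pd.DataFrame:
    """Per-stage AS table: count and within-stage percentage per category."""
    rows = []
    for stage in stages:
        counts = stage_counts[stage]
        total = sum(counts.get(c, 0) for c in EVENT_CATEGORIES)
        for cat in EVENT_CATEGORIES:
            n = counts.get(cat, 0)
            rows.append((stage, cat, n, percent(n, total)))
        rows.append((stage, "total", total, percent(total, total)))
    return pd.DataFrame(rows, columns=["stage", "category", "count", "percent"])


def render_de_table(de_table: pd.DataFrame, only_de: bool = False) -> pd.DataFrame:
    """DE gene table with Max/Min and FDR columns."""
    out = de_table.copy()
    out = out.rename(columns={"maxmin_ratio": "max_min", "adjusted_p": "fdr"})
    if only_de:
        out = out[out["is_de"]]
    return out


def write_tables(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Write each table as <name>.tsv and <name>.json under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        tsv = out / f"{name}.tsv"
        table.to_csv(tsv, sep="\t", index=bool(table.index.name or table.index.names[0]))
        js = out / f"{name}.json"
        js.write_text(json.dumps(
            json.loads(table.reset_index().to_json(orient="records")), indent=1
        ))
        paths[name] = tsv
    return paths
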