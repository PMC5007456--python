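"""FPKM normalization, replicate QC, trace filtering, and the
fold-ratio / BH-adjusted differential-expression gate.

The DE gate itself is: max/min stage-mean FPKM ratio >= 2 and BH-adjusted
P < 0.01. P-values come from a one-way fixed-effects F-test on
log2(FPKM + 1). With only two or three replicates per stage a per-gene
residual variance on 3-6 degrees of freedom is too unstable to reach useful
power, so the default test pools the residual variance across all genes
(homoscedastic log-scale noise); ``variance="per_gene"`` gives the plain
textbook per-gene ANOVA, and externally computed p-values can be supplied
instead of either.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "DEResult",
    "ReplicateQC",
    "compute_fpkm",
    "stage_means",
    "replicate_qc",
    "filter_trace",
    "maxmin_ratio",
    "anova_f",
    "f_test_table",
    "bh_adjust",
    "call_de",
    "run_de",
]

RATIO_FLOOR = 0.01  # stands in for a zero minimum when forming max/min ratios


@dataclass
class CountMatrix:
    """Fragment counts with a (stage, replicate) column MultiIndex and
    per-column total mapped fragments."""

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.counts.columns, pd.MultiIndex):
            raise ValueError("counts columns must be a (stage, replicate) MultiIndex")
        sums = self.counts.sum(axis=0)
        if (self.totals < sums - 0.5).any():
            raise ValueError("column totals smaller than assigned counts")

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.counts.columns.get_level_values(0)))


@dataclass
class ReplicateQC:
    correlations: dict[str, pd.DataFrame]
    excluded: list[tuple[str, str]] = field(default_factory=list)
    skipped_stages: list[str] = field(default_factory=list)


@dataclass
class DEResult:
    table: pd.DataFrame  # per gene: stage means, maxmin_ratio, raw_p, adjusted_p, is_de
    flagged_zero_min: list[str] = field(default_factory=list)


def compute_fpkm(counts: CountMatrix, lengths: Mapping[str, float]) -> pd.DataFrame:
    """FPKM = count * 1e9 / (effective_length_bp * total_mapped_fragments)."""
    missing = [i for i in counts.counts.index if i not in lengths]
    if missing:
        raise KeyError(f"missing effective length for {missing[0]!r}")
    if (counts.totals <= 0).any():
        raise ValueError("total mapped fragments must be > 0")
    length_bp = pd.Series({i: float(lengths[i]) for i in counts.counts.index})
    return counts.counts.mul(1e9).div(counts.totals, axis=1).div(length_bp, axis=0)


def stage_means(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Mean FPKM per stage (columns collapse from (stage, replicate))."""
    return fpkm.T.groupby(level=0, sort=False).mean().T


def replicate_qc(fpkm: pd.DataFrame, threshold: float = 0.85) -> ReplicateQC:
    """Pearson correlation on log2(FPKM+1) between replicates of a stage.

    A replicate is excluded when its correlation with every other replicate
    of its stage falls strictly below the threshold. Stages with a single
    replicate are skipped with a warning.
    """
    qc = ReplicateQC(correlations={})
    logx = np.log2(fpkm + 1.0)
    for stage in dict.fromkeys(fpkm.columns.get_level_values(0)):
        block = logx[stage]
        if block.shape[1] < 2:
            logger.warning("stage %s has a single replicate; QC skipped", stage)
            qc.skipped_stages.append(stage)
            continue
        corr = block.corr(method="pearson")
        qc.correlations[stage] = corr
        for rep in corr.columns:
            others = corr.loc[rep].drop(rep)
            if (others < threshold).all():
                qc.excluded.append((stage, rep))
    return qc


def filter_trace(
    stage_fpkm: pd.DataFrame, eps: float = 0.01
) -> tuple[list[str], list[str]]:
    """Drop ids whose FPKM is below eps at every stage."""
    silent = (stage_fpkm < eps).all(axis=1)
    return list(stage_fpkm.index[~silent]), list(stage_fpkm.index[silent])


def maxmin_ratio(means: Sequence[float]) -> tuple[float, bool]:
    """Ratio of the maximum to the minimum stage mean.

    A zero minimum is replaced by a 0.01 floor and flagged; an all-zero
    vector is undefined (NaN, flagged).
    """
    arr = np.asarray(means, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 stage means")
    hi, lo = float(arr.max()), float(arr.min())
    if hi == 0.0:
        return float("nan"), True
    if lo == 0.0:
        return hi / RATIO_FLOOR, True
    return hi / lo, False


def anova_f(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects F statistic with its upper-tail p-value.

    Operates on the values as given (callers pass log2(FPKM+1)). Degenerate
    inputs follow fixed conventions: all values identical -> F=0, p=1;
    zero residual variance with unequal means -> F=inf, p=0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need >= 2 groups")
    n = sum(a.size for a in arrays)
    if n - k < 1:
        raise ValueError("need >= 1 residual degree of freedom")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        logger.warning("zero residual variance with unequal means; p = 0")
        return float("inf"), 0.0
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def f_test_table(
    log_expr: pd.DataFrame, variance: str = "pooled"
) -> pd.DataFrame:
    """Vectorized one-way F-test per row of a (stage, replicate) table.

    ``variance="pooled"`` (default) uses a residual variance pooled across
    all rows, with the correspondingly large denominator df;
    ``variance="per_gene"`` is the plain per-row ANOVA.
    """
    if variance not in {"pooled", "per_gene"}:
        raise ValueError(f"unknown variance mode {variance!r}")
    stages = list(dict.fromkeys(log_expr.columns.get_level_values(0)))
    k = len(stages)
    x = log_expr.to_numpy(dtype=float)
    n = x.shape[1]
    group_idx = [np.flatnonzero(log_expr.columns.get_level_values(0) == s) for s in stages]
    grand = x.mean(axis=1)
    ss_between = np.zeros(len(x))
    ss_within = np.zeros(len(x))
    for idx in group_idx:
        sub = x[:, idx]
        m = sub.mean(axis=1)
        ss_between += idx.size * (m - grand) ** 2
        ss_within += ((sub - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n - k
    if variance == "pooled":
        pooled = ss_within.sum() / (df_w * len(x))
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_between / df_b) / pooled
        p = stats.f.sf(f, df_b, df_w * len(x))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_between / df_b) / (ss_within / df_w)
        f = np.where((ss_within == 0) & (ss_between == 0), 0.0, f)
        f = np.where((ss_within == 0) & (ss_between > 0), np.inf, f)
        p = stats.f.sf(f, df_b, df_w)
    return pd.DataFrame({"F": f, "raw_p": p}, index=log_expr.index)


def bh_adjust(raw_p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving by index."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(ratio: float, adjusted_p: float) -> bool:
    """DE when max/min ratio >= 2 and BH-adjusted P < 0.01."""
    return bool(ratio >= 2.0 and adjusted_p < 0.01)


def run_de(
    counts: CountMatrix,
    lengths: Mapping[str, float],
    ratio_threshold: float = 2.0,
    p_threshold: float = 0.01,
    qc_threshold: float = 0.85,
    variance: str = "pooled",
    external_p: Optional[Mapping[str, float]] = None,
    apply_qc: bool = True,
) -> DEResult:
    """Full DE pass: FPKM, replicate QC, F-test, BH, gate."""
    fpkm = compute_fpkm(counts, lengths)
    if apply_qc:
        qc = replicate_qc(fpkm, qc_threshold)
        if qc.excluded:
            drop = [c for c in fpkm.columns if (c[0], c[1]) in set(qc.excluded)]
            logger.info("excluding replicates failing QC: %s", qc.excluded)
            fpkm = fpkm.drop(columns=drop)
    means = stage_means(fpkm)

    ratios = np.empty(len(means))
    flagged: list[str] = []
    for i, (gid, row) in enumerate(zip(means.index, means.to_numpy())):
        ratios[i], flag = maxmin_ratio(row)
        if flag:
            flagged.append(gid)

    if external_p is not None:
        raw_p = np.array([external_p[g] for g in means.index], dtype=float)
    else:
        raw_p = f_test_table(np.log2(fpkm + 1.0), variance=variance)["raw_p"].to_numpy()
    adj_p = bh_adjust(raw_p)

    table = means.copy()
    table["maxmin_ratio"] = ratios
    table["raw_p"] = raw_p
    table["adjusted_p"] = adj_p
    table["is_de"] = [
        bool(r >= ratio_threshold and q < p_threshold)
        for r, q in zip(ratios, adj_p)
    ]
    return DEResult(table=table, flagged_zero_min=flagged)
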