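"""Paused-polymerase vs meiotic double-strand-break analysis.

DSB maps (SPO11-oligo-like reads) concentrate just downstream of active
TSSs.  This module quantifies that association: promoters are filtered by a
minimum nascent read count, stratified into quartiles of promoter signal,
DSB reads are summed in a +/-500 nt TSS flank (strand-agnostic: breaks have
no strand), and the promoter-DSB relationship is summarized by Spearman
correlation and between-quartile rank tests.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .tracks import SignalTrack


def promoter_filter(promoter_reads: pd.Series, min_reads: float = 5) -> pd.Index:
    """Genes whose promoter read count reaches ``min_reads`` (strict < removed)."""
    return promoter_reads.index[promoter_reads >= min_reads]


def quartile_stratify(promoter_reads: pd.Series) -> pd.Series:
    """Quartile labels Q1 (highest signal) .. Q4 (lowest), deterministic.

    Genes are sorted descending by key with ties broken by gene id; group
    sizes are floor(n/4) with the remainder assigned to the lowest
    quartiles, so at n = 14,804 every quartile holds 3,701 genes.
    """
    df = promoter_reads.rename("key").reset_index()
    df.columns = ["gene_id", "key"]
    df = df.sort_values(["key", "gene_id"], ascending=[False, True], kind="mergesort")
    n = len(df)
    base = n // 4
    sizes = [base] * 4
    for i in range(n - 4 * base):   # remainder to the lowest quartiles
        sizes[3 - i] += 1
    labels = np.repeat([f"Q{i+1}" for i in range(4)], sizes)
    return pd.Series(labels, index=df["gene_id"], name="quartile")


def dsb_promoter_sum(dsb: SignalTrack, genes: Sequence[GeneModel],
                     flank: int = 500) -> pd.Series:
    """Per-gene DSB reads in [TSS - flank, TSS + flank], strand-agnostic."""
    sums = {}
    for g in genes:
        lo = max(g.tss - flank, 0)
        sums[g.gene_id] = dsb.window_sum(g.chrom, lo, g.tss + flank + 1)
    return pd.Series(sums, name="dsb_reads")


def pause_dsb_correlation(promoter_reads: pd.Series, dsb_sums: pd.Series
                          ) -> Tuple[float, int]:
    """Spearman rho (average-rank ties) between promoter signal and DSB sums."""
    common = promoter_reads.index.intersection(dsb_sums.index)
    rho = stats.spearmanr(promoter_reads.loc[common], dsb_sums.loc[common]).statistic
    return float(rho), len(common)


def quartile_dsb_comparison(quartiles: pd.Series, dsb_sums: pd.Series,
                            paired: bool = False) -> pd.DataFrame:
    """Adjacent-quartile two-sided rank tests on DSB sums plus medians.

    Quartile groups are unpaired samples, so the default test is the
    Mann-Whitney rank-sum; a paired (signed-rank) variant is available for
    genuinely paired inputs of equal length.  Single-element groups make
    the test undefined and are flagged with a NaN p.
    """
    order = ["Q1", "Q2", "Q3", "Q4"]
    groups = {q: dsb_sums.loc[quartiles.index[quartiles == q]].dropna()
              for q in order}
    rows = []
    for a, b in zip(order[:-1], order[1:]):
        ga, gb = groups[a], groups[b]
        if len(ga) < 2 or len(gb) < 2 or (paired and len(ga) != len(gb)):
            p = np.nan
        elif paired:
            p = float(stats.wilcoxon(ga.to_numpy(), gb.to_numpy()).pvalue)
        else:
            p = float(stats.mannwhitneyu(ga, gb, alternative="two-sided").pvalue)
        rows.append({"pair": f"{a}_vs_{b}",
                     "median_a": float(np.median(ga)) if len(ga) else np.nan,
                     "median_b": float(np.median(gb)) if len(gb) else np.nan,
                     "p": p})
    out = pd.DataFrame(rows).set_index("pair")
    medians = [float(np.median(groups[q])) if len(groups[q]) else np.nan
               for q in order]
    out.attrs["medians"] = dict(zip(order, medians))
    out.attrs["monotone_decreasing"] = bool(
        all(x > y for x, y in zip(medians[:-1], medians[1:]))
    )
    return out
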