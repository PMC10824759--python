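"""Strand-aware promoter/gene-body quantification and metagene profiles.

Promoter window: [TSS, TSS + 150) in the gene direction — where paused
polymerase sits.  Gene body: [TSS + 250, TES], closing at the TES
inclusive — productive elongation.  On the minus strand both windows extend
toward decreasing coordinates.  Genes whose TES lies within the body offset
of the TSS get undefined body fields rather than zeros, which would
otherwise produce spurious infinite pausing indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .tracks import SignalTrack


@dataclass
class WindowSignal:
    gene_id: str
    promoter_reads: float
    promoter_density: float
    body_reads: Optional[float]
    body_density: Optional[float]

    @property
    def body_defined(self) -> bool:
        return self.body_reads is not None


def _gene_direction_interval(gene: GeneModel, start_off: int, end_off: int
                             ) -> Tuple[int, int]:
    """Genomic half-open [lo, hi) for gene-direction offsets [start_off, end_off)."""
    if gene.strand == "+":
        return gene.tss + start_off, gene.tss + end_off
    return gene.tss - end_off + 1, gene.tss - start_off + 1


def window_signal(track: SignalTrack, gene: GeneModel,
                  promoter_len: int = 150, body_offset: int = 250) -> WindowSignal:
    """Promoter and body sums/densities for one gene on its own strand."""
    if track.strand != gene.strand:
        raise ValueError(
            f"track strand {track.strand} does not match gene {gene.gene_id} "
            f"strand {gene.strand}"
        )
    lo, hi = _gene_direction_interval(gene, 0, promoter_len)
    promoter = track.window_sum(gene.chrom, lo, hi)
    gene_len = gene.length  # TSS..TES inclusive
    if gene_len - 1 <= body_offset:
        # TES within the offset: body window empty / degenerate
        return WindowSignal(gene.gene_id, promoter, promoter / promoter_len,
                            None, None)
    lo, hi = _gene_direction_interval(gene, body_offset, gene_len)  # ..TES inclusive
    body = track.window_sum(gene.chrom, lo, hi)
    body_len = gene_len - body_offset
    return WindowSignal(gene.gene_id, promoter, promoter / promoter_len,
                        body, body / body_len)


def window_signal_table(track: SignalTrack, genes: Sequence[GeneModel],
                        promoter_len: int = 150, body_offset: int = 250
                        ) -> pd.DataFrame:
    rows = []
    for g in genes:
        if g.strand != track.strand:
            continue
        ws = window_signal(track, g, promoter_len, body_offset)
        rows.append({"gene_id": ws.gene_id,
                     "promoter_reads": ws.promoter_reads,
                     "promoter_density": ws.promoter_density,
                     "body_reads": ws.body_reads,
                     "body_density": ws.body_density})
    return pd.DataFrame(rows).set_index("gene_id")


def pausing_index(ws: WindowSignal) -> float:
    """Promoter density over body density; NaN when the body is undefined
    or empty (flagging, not a value)."""
    if not ws.body_defined or ws.body_density == 0:
        return math.nan
    return ws.promoter_density / ws.body_density


@dataclass
class MetageneProfile:
    bin_offsets: np.ndarray   # nt relative to TSS, left edge of each bin
    mean_signal: np.ndarray   # per-bin sum over TSSs / n_tss
    n_tss: int
    bin_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.bin_offsets, "mean": self.mean_signal})


def metagene(track: SignalTrack, tss_list: Sequence[Tuple[str, int, str]],
             bin_size: int = 20, range_nt: Tuple[int, int] = (-500, 1500)
             ) -> MetageneProfile:
    """Composite profile around TSSs: per-bin read sums divided by n_tss.

    ``tss_list`` holds (chrom, tss, strand); offsets are strand-aware with
    downstream positive.  ``range_nt`` is [upstream, downstream) and must be
    divisible into whole bins.
    """
    lo, hi = range_nt
    span = hi - lo
    if span <= 0 or span % bin_size != 0:
        raise ValueError("bin_size must divide the metagene range")
    n_bins = span // bin_size
    sums = np.zeros(n_bins)
    for chrom, tss, strand in tss_list:
        pos, val = track.chrom_arrays(chrom)
        if strand == "+":
            g_lo, g_hi = tss + lo, tss + hi
            i0, i1 = np.searchsorted(pos, (g_lo, g_hi), side="left")
            offs = pos[i0:i1] - tss
        else:
            g_lo, g_hi = tss - hi + 1, tss - lo + 1
            i0, i1 = np.searchsorted(pos, (g_lo, g_hi), side="left")
            offs = tss - pos[i0:i1]
        idx = (offs - lo) // bin_size
        np.add.at(sums, idx.astype(int), val[i0:i1])
    n_tss = len(tss_list)
    mean = sums / n_tss if n_tss else sums
    offsets = np.arange(lo, hi, bin_size)
    return MetageneProfile(offsets, mean, n_tss, bin_size)


def relative_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene fraction of the maximum across stages (row max -> 1).

    Rows (genes) are divided by their row maximum so the stage with the
    highest signal scores 1; all-zero rows are excluded (their relative
    profile is undefined).
    """
    if values.shape[1] < 1:
        raise ValueError("need at least one stage column")
    row_max = values.max(axis=1)
    keep = row_max > 0
    return values.loc[keep].div(row_max[keep], axis=0)


def heatmap_matrix(matrices: Dict[str, pd.DataFrame], gene_order: Sequence[str]
                   ) -> Dict[str, pd.DataFrame]:
    """Align several per-gene matrices to one row order (e.g. cluster order
    or descending promoter signal of a named stage)."""
    order = list(gene_order)
    out = {}
    for name, mat in matrices.items():
        unknown = set(order) - set(mat.index)
        if unknown:
            raise KeyError(f"{name}: unknown genes in order: {sorted(unknown)[:5]}")
        out[name] = mat.loc[order]
    return out


def rank_by_signal(signal: pd.Series) -> List[str]:
    """Gene ids sorted by descending signal, ties broken by gene id."""
    df = signal.rename("key").reset_index()
    df.columns = ["gene_id", "key"]
    df = df.sort_values(["key", "gene_id"], ascending=[False, True], kind="mergesort")
    return df["gene_id"].tolist()
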