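"""TSS refinement from nascent-RNA 5' ends and activity calling.

Annotated TSSs are imprecise; the 5' ends of nascent RNA mark actual start
positions at base resolution.  A gene is called active when the pooled,
unnormalized 5' reads within a 1 kb window around its annotated TSS reach a
minimum count (default 8), and its TSS is then re-aligned to the position
with the maximal 5' count.  The 1 kb window is interpreted as centered,
+/-500 nt around the annotated start.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .tracks import SignalTrack, pool_tracks


def refine_tss(gene: GeneModel, five_prime: SignalTrack,
               min_reads: int = 8, window: int = 1000) -> GeneModel:
    """Re-align one gene's TSS to the 5'-end maximum, or mark it inactive.

    The search window is ``window`` nt wide, centered on the annotated TSS.
    With total 5' reads in the window >= ``min_reads`` the gene becomes
    active and its TSS moves to the position of maximal count; ties go to
    the most upstream tied position (strand-aware).  Otherwise the TSS is
    left unchanged and the gene is inactive.
    """
    half = window // 2
    lo = gene.tss - half
    hi = gene.tss + half + 1  # half-open; includes tss+half
    if lo < 0:
        warnings.warn(f"{gene.gene_id}: search window truncated at chromosome start")
        lo = 0
    pos, val = five_prime.chrom_arrays(gene.chrom)
    i0 = np.searchsorted(pos, lo, side="left")
    i1 = np.searchsorted(pos, hi, side="left")
    wpos, wval = pos[i0:i1], val[i0:i1]
    # candidate starts must stay upstream of the TES, otherwise a short
    # gene could capture a same-strand neighbour's 5' peak
    inside = wpos < gene.tes if gene.strand == "+" else wpos > gene.tes
    wpos, wval = wpos[inside], wval[inside]
    if len(wpos) == 0 or wval.sum() < min_reads:
        return gene.with_tss(gene.tss, active=False)
    best = wval.max()
    tied = wpos[wval == best]
    # most upstream in gene direction
    new_tss = int(tied.min() if gene.strand == "+" else tied.max())
    return gene.with_tss(new_tss, active=True)


def refine_all(genes: Sequence[GeneModel],
               five_prime_tracks: Dict[str, Iterable[SignalTrack]],
               min_reads: int = 8, window: int = 1000,
               ) -> Tuple[List[GeneModel], pd.DataFrame]:
    """Refine every gene against pooled per-strand 5' tracks.

    ``five_prime_tracks`` maps strand -> iterable of unnormalized 5' tracks
    (all samples); pooling before refinement follows the convention that raw
    evidence, not normalized signal, drives annotation.  Returns the refined
    annotation and an activity summary (n_active plus biotype breakdown of
    the active set).
    """
    pooled = {s: pool_tracks(ts) for s, ts in five_prime_tracks.items()}
    refined = []
    for g in genes:
        track = pooled.get(g.strand)
        if track is None:
            refined.append(g.with_tss(g.tss, active=False))
        else:
            refined.append(refine_tss(g, track, min_reads=min_reads, window=window))
    active = [g for g in refined if g.active]
    breakdown = pd.Series([g.biotype for g in active]).value_counts()
    summary = pd.DataFrame({
        "metric": ["n_genes", "n_active"] + [f"active_{b}" for b in breakdown.index],
        "value": [len(refined), len(active)] + breakdown.tolist(),
    })
    return refined, summary


def select_tes(gene: GeneModel, candidate_tes: Sequence[int],
               rnaseq_coverage: SignalTrack, tail: int = 500) -> GeneModel:
    """Pick the candidate TES with maximal mean RNA-seq coverage over its
    final ``tail`` nt; single candidates pass through unchanged."""
    if len(candidate_tes) == 0:
        return gene
    if len(candidate_tes) == 1:
        return gene if candidate_tes[0] == gene.tes else _with_tes(gene, candidate_tes[0])
    best, best_cov = None, -1.0
    for tes in candidate_tes:
        if gene.strand == "+":
            lo, hi = max(gene.tss + 1, tes - tail + 1), tes + 1
        else:
            lo, hi = tes, min(gene.tss, tes + tail)
        cov = rnaseq_coverage.window_sum(gene.chrom, lo, hi) / max(hi - lo, 1)
        if cov > best_cov:
            best, best_cov = tes, cov
    return _with_tes(gene, best)


def _with_tes(gene: GeneModel, tes: int) -> GeneModel:
    from dataclasses import replace
    return replace(gene, tes=tes)
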