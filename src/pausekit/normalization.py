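"""Spike-in normalization with genome-copy (ploidy) correction.

Two conventions are used depending on assay.  RNA-seq size factors are
``mapped reference reads / mapped spike reads`` per sample; PRO-seq tracks
are instead rescaled to the sample with the lowest spike reads.  In both,
haploid round-spermatid samples get their factor halved (equivalently their
scale halved), so that signal reads out per genome copy relative to the
diploid reference: a haploid cell carries one genome copy, so equal per-cell
spike recovery implies twice the apparent per-copy signal without the
correction.  4C meiotic cells receive no extra correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .annotation import GeneModel
from .tracks import SignalTrack


@dataclass
class SpikeFactor:
    sample: str
    ref_reads: float
    spike_reads: float
    ploidy: int
    factor: float

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 (haploid) or 2 (diploid)")
        if self.factor <= 0:
            raise ValueError("spike factor must be positive")


def spike_factor(ref_reads: float, spike_reads: float, ploidy: int,
                 sample: str = "") -> SpikeFactor:
    """Per-sample size factor: ref/spike, halved for haploid samples."""
    if spike_reads <= 0:
        raise ValueError("spike_reads must be > 0 to define a spike factor")
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    factor = (ref_reads / spike_reads) * (1.0 if ploidy == 2 else 0.5)
    return SpikeFactor(sample=sample, ref_reads=ref_reads,
                       spike_reads=spike_reads, ploidy=ploidy, factor=factor)


def normalize_to_min_spike(factors: Sequence[SpikeFactor]) -> Dict[str, float]:
    """Track scales relative to the lowest-spike sample.

    scale = spike_min / spike_sample, then halved for haploid samples; the
    minimum-spike diploid sample keeps scale 1.
    """
    if not factors:
        raise ValueError("need at least one sample")
    spike_min = min(f.spike_reads for f in factors)
    scales = {}
    for f in factors:
        scale = spike_min / f.spike_reads
        if f.ploidy == 1:
            scale *= 0.5
        scales[f.sample] = scale
    return scales


def proseq_size_factors(factors: Sequence[SpikeFactor]) -> "pd.Series":
    """Spike-read size factors for count-level nascent-RNA DE (divisors).

    sf = spike_reads / spike_reads_min, halved for haploid samples.  Under
    the count/sf convention this doubles haploid normalized signal, i.e.
    reads out transcription per genome copy, and removes per-sample depth
    exactly because spike material is added per cell.
    """
    if not factors:
        raise ValueError("need at least one sample")
    spike_min = min(f.spike_reads for f in factors)
    return pd.Series({
        f.sample: (f.spike_reads / spike_min) * (0.5 if f.ploidy == 1 else 1.0)
        for f in factors
    })


def apply_scale(obj, scale: float):
    """Multiply a track or count table by a positive scale."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if isinstance(obj, SignalTrack):
        return obj.scaled(scale)
    return obj * scale


def factors_table(factors: Sequence[SpikeFactor],
                  scales: Dict[str, float] | None = None) -> pd.DataFrame:
    rows = []
    for f in factors:
        rows.append({
            "sample": f.sample, "ref_reads": f.ref_reads,
            "spike_reads": f.spike_reads, "ploidy": f.ploidy,
            "factor": f.factor,
            "scale": None if scales is None else scales.get(f.sample),
        })
    return pd.DataFrame(rows)


def promoter_sums(track: SignalTrack, genes: Iterable[GeneModel],
                  window: int = 150) -> pd.Series:
    """Per-gene read sums over the first ``window`` nt downstream of the TSS."""
    sums = {}
    for g in genes:
        if g.strand == "+":
            s = track.window_sum(g.chrom, g.tss, g.tss + window)
        else:
            s = track.window_sum(g.chrom, g.tss - window + 1, g.tss + 1)
        sums[g.gene_id] = s
    return pd.Series(sums, name="promoter_reads")


def replicate_qc(tracks: Dict[str, SignalTrack], genes: Sequence[GeneModel],
                 window: int = 150, min_rho: float = 0.9) -> pd.DataFrame:
    """Pairwise Spearman correlations of per-gene promoter sums.

    Replicate agreement is judged on reads summed over the first 150 bp
    downstream of each TSS; average ranks are used for ties, which are
    common at low depth.  Pairs below ``min_rho`` are flagged.
    """
    per_rep = pd.DataFrame({name: promoter_sums(t, genes, window)
                            for name, t in tracks.items()})
    rows = []
    for a, b in combinations(per_rep.columns, 2):
        rho = spearmanr(per_rep[a], per_rep[b]).statistic
        rows.append({"rep_a": a, "rep_b": b, "spearman_rho": rho,
                     "flagged": bool(rho < min_rho)})
    return pd.DataFrame(rows)
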