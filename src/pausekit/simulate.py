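"""Synthetic staged-germ-cell data with known ground truth.

The generator plants every structure the analysis assumes so each
downstream statistic can be tested against truth:

* three cell stages — mitotic spermatogonia (SG, diploid), meiotic
  spermatocytes (SC, diploid) and post-meiotic round spermatids (RS,
  haploid) — with six expression programs (archetypal relative profiles);
* promoter-proximal pause peaks: nascent-RNA 3' ends 20-60 nt downstream
  of the true TSS, 5' ends exactly at it, body reads uniform from
  TSS+250 to the TES;
* spike-in chimerism (spike reads proportional to per-sample depth) and
  the haploid genome-copy difference, including dosage compensation:
  per-cell output of flat-profile genes is preserved across meiosis by
  doubling per-copy transcription in RS;
* divergent mRNA-lncRNA pairs within 1 kb, biotype mix, and shorter genes
  in the late (RS-activated) program;
* genotype knockout effects on designated gene subsets for pseudobulk DE,
  single-cell libraries with planted QC failures;
* TSS-proximal DSB (SPO11-like) hotspots whose rate is a noisy monotone
  function of SG pause strength with a target rank correlation.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotation import GeneModel
from .counts import CountMatrix
from .tracks import SignalTrack

STAGES = ("SG", "SC", "RS")
PLOIDY = {"SG": 2, "SC": 2, "RS": 1}

# Archetypal relative expression (per-cell RNA) across SG, SC, RS.
# Program 6 is the late, RS-activated program (lncRNA-rich, short genes);
# program 4 is the SC-induced program regulated by pause release; program 5
# is flat across SC->RS, i.e. per-cell output preserved through meiosis
# (the dosage-compensated cohort).
ARCHETYPES = np.array([
    [1.00, 0.10, 0.05],   # 1: SG-high, rapidly repressed
    [1.00, 0.50, 0.35],   # 2: slowly repressed
    [0.30, 1.00, 0.65],   # 3: SC-activated, partly maintained
    [0.05, 1.00, 0.15],   # 4: SC-specific (pause-release regulated)
    [0.55, 1.00, 1.00],   # 5: SC-activated, flat into RS (compensated)
    [0.05, 0.20, 1.00],   # 6: RS-specific (late program)
])

# Program mix chosen so total per-cell RNA (profile x expected length) is
# nearly equal across stages: constant total cellular RNA is what makes
# reference/spike factors valid per-cell normalizers, and residual
# imbalance is < 0.1 log2.
PROGRAM_WEIGHTS = np.array([0.225, 0.10, 0.10, 0.10, 0.175, 0.30])

# Promoter pause strength profile; programs other than 4 pause in
# proportion to expression, program 4 is paused in SG and released in SC
# (promoter max and body max fall in different stages).
PAUSE_PROFILES = np.array([
    [1.00, 0.10, 0.05],
    [1.00, 0.50, 0.35],
    [0.30, 1.00, 0.65],
    [1.00, 0.35, 0.10],   # 4: promoter peaks in SG, body peaks in SC
    [0.55, 1.00, 1.00],
    [0.05, 0.20, 1.00],
])


@dataclass
class SimulationParams:
    """Study conditions for the synthetic dataset (defaults are the ones
    every test and driver runs under; see docs/methods.md)."""

    n_genes: int = 2000
    genome_len: int = 60_000_000
    chrom: str = "chr1"
    n_reps: int = 3
    # gene geometry
    length_meanlog: float = float(np.log(8000.0))
    length_sdlog: float = 0.6
    min_length: int = 600
    late_length_scale: float = 0.5      # program-6 genes are shorter
    intergenic_mean: int = 4000
    # biotypes (active-promoter mix: ~82% coding, ~16% lncRNA)
    frac_protein_coding: float = 0.80
    frac_lncrna: float = 0.15
    pair_fraction: float = 0.5          # of lncRNAs: divergent partner of an mRNA
    # expression
    body_rate_meanlog: float = float(np.log(12.0))   # reads/kb per cell at profile 1
    body_rate_sdlog: float = 0.6
    pause_meanlog: float = float(np.log(60.0))       # promoter reads per cell at profile 1
    pause_sdlog: float = 0.6
    tss_annotation_jitter: int = 120    # sd of annotated-TSS error, nt
    rep_noise_sd: float = 0.10          # gene-level lognormal replicate noise
    depth_sdlog: float = 0.20           # per-sample depth variation
    spike_reads_base: float = 2.0e4     # spike reads at depth 1
    # RNA-seq counts
    rna_scale: float = 2.0              # counts per (reads/kb x kb) unit
    dispersion: float = 0.05
    n_spike_rows: int = 30
    # pause geometry
    pause_offset_lo: int = 20
    pause_offset_hi: int = 60           # inclusive
    body_offset: int = 250
    # DSB
    dsb_rho: float = 0.44               # target Spearman with SG pause strength
    dsb_mean_reads: float = 30.0
    dsb_offset: int = 100               # downstream of TSS
    dsb_sd: float = 120.0
    # single cell
    sc_lib_meanlog: float = float(np.log(12000.0))
    sc_lib_sdlog: float = 0.20
    sc_fail_low_frac: float = 0.08
    sc_fail_mito_frac: float = 0.08
    sc_fail_lib_scale: float = 0.10
    sc_mito_frac_normal: float = 0.03
    sc_mito_frac_fail: float = 0.30
    n_mito_genes: int = 13
    n_effect_genes: int = 60
    sc_effect_log2: float = -2.0        # knockout effect on designated genes
    genotype_samples: Dict[str, int] = field(
        default_factory=lambda: {"control": 4, "koA": 2, "koB": 3})


@dataclass
class SynthTruth:
    """Ground truth behind one synthetic dataset."""

    params: SimulationParams
    genes: pd.DataFrame            # per-gene geometry, biotype, program, baselines
    percell_rate: pd.DataFrame     # genes x stages: per-cell body reads per kb
    pause_strength: pd.DataFrame   # genes x stages: per-cell promoter reads
    dsb_rate: pd.Series            # expected SPO11-like reads near each TSS
    mito_genes: List[str]
    effect_genes: Dict[str, List[str]]   # genotype -> down-shifted genes
    sample_depth: Dict[str, float]       # PRO-seq per-sample depth factors

    def stage_of(self, sample: str) -> str:
        return sample.split("_")[0]

    def gene_models(self, annotated: bool = True) -> List[GeneModel]:
        """GeneModel list using annotated (jittered) or true TSSs."""
        col = "tss" if annotated else "true_tss"
        out = []
        for gid, row in self.genes.iterrows():
            out.append(GeneModel(
                gene_id=gid, chrom=row["chrom"], strand=row["strand"],
                tss=int(row[col]), tes=int(row["tes"]), biotype=row["biotype"],
            ))
        return out


# ---------------------------------------------------------------------------
# Annotation / truth
# ---------------------------------------------------------------------------

def simulate_annotation(params: SimulationParams | None = None,
                        seed: int = 0) -> Tuple[List[GeneModel], SynthTruth]:
    """Lay out non-overlapping genes on both strands with planted programs.

    A configurable fraction of lncRNAs is placed as the divergent
    (antisense, TSS within 1 kb) partner of a protein-coding gene, both
    members sharing the late program — the structure behind coordinated
    mRNA-lncRNA pair calling.
    """
    p = params or SimulationParams()
    rng = np.random.default_rng(seed)
    n = p.n_genes
    if n == 0:
        return [], _empty_truth(p)

    programs = rng.choice(6, size=n, p=PROGRAM_WEIGHTS) + 1
    biotype = np.where(
        rng.random(n) < p.frac_protein_coding, "protein_coding",
        np.where(rng.random(n) < p.frac_lncrna / max(1 - p.frac_protein_coding, 1e-9),
                 "lncRNA", "other"),
    )
    lengths = np.exp(rng.normal(p.length_meanlog, p.length_sdlog, n))
    lengths = np.where(programs == 6, lengths * p.late_length_scale, lengths)
    lengths = np.maximum(lengths.astype(int), p.min_length)

    # divergent pairs: mark some lncRNAs as partners of program-6 mRNAs
    lnc_idx = np.flatnonzero(biotype == "lncRNA")
    n_pairs = int(round(p.pair_fraction * len(lnc_idx)))
    partner_of = np.full(n, -1)  # lncRNA index -> will be placed next to previous mRNA
    pair_lncs = rng.choice(lnc_idx, size=n_pairs, replace=False) if n_pairs else []

    pair_lnc_set = set(int(j) for j in pair_lncs)
    rows = []
    cursor = 1000
    unused_mrna: int | None = None     # row index of a pairable + strand mRNA
    mrna_left_bound = 0                # leftmost free base upstream of it
    for i in range(n):
        length = int(lengths[i])
        gap = int(rng.exponential(p.intergenic_mean)) + 1200
        if i in pair_lnc_set and unused_mrna is not None:
            # divergent partner: minus-strand lncRNA whose TSS lies within
            # 1 kb upstream of the mRNA TSS, transcribed away from it into
            # the (free) upstream gap
            m = rows[unused_mrna]
            m_gap = m["start"] - mrna_left_bound     # free upstream span
            d = int(rng.integers(100, min(1000, m_gap - 600)))
            tss = m["tss"] - d
            tes = max(tss - length, mrna_left_bound)
            if tss - tes >= 500:
                rows.append({"gene_id": f"g{i:05d}", "chrom": p.chrom,
                             "strand": "-", "tss": tss, "tes": tes,
                             "start": tes, "end": tss + 1,
                             "length": tss - tes + 1, "biotype": "lncRNA",
                             "program": 6, "paired_with": m["gene_id"]})
                m["program"] = 6
                unused_mrna = None
                continue
        start = cursor + gap
        end = start + length
        if end >= p.genome_len:
            raise ValueError(
                f"genome_len={p.genome_len} too small for {n} genes; "
                f"placed {len(rows)} before running out"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
        rows.append({"gene_id": f"g{i:05d}", "chrom": p.chrom, "strand": strand,
                     "tss": tss, "tes": tes, "start": start, "end": end,
                     "length": length, "biotype": biotype[i],
                     "program": int(programs[i]), "paired_with": ""})
        if biotype[i] == "protein_coding" and strand == "+":
            unused_mrna = len(rows) - 1
            mrna_left_bound = cursor + 1
        cursor = end

    genes = pd.DataFrame(rows).set_index("gene_id")
    m = len(genes)

    # annotated TSS = true TSS + jitter (bounded so it stays inside the gene
    # neighbourhood and the refinement window)
    jit = rng.normal(0, p.tss_annotation_jitter, m)
    jit = np.clip(jit, -400, 400).astype(int)
    sign = np.where(genes["strand"] == "+", 1, -1)
    genes["true_tss"] = genes["tss"]
    genes["tss"] = genes["tss"] + sign * np.abs(jit)  # annotated downstream-shifted
    # keep tss strictly inside (tss < tes for +; tss > tes for -)
    plus = genes["strand"] == "+"
    genes.loc[plus, "tss"] = np.minimum(genes.loc[plus, "tss"],
                                        genes.loc[plus, "tes"] - p.body_offset - 100)
    genes.loc[~plus, "tss"] = np.maximum(genes.loc[~plus, "tss"],
                                         genes.loc[~plus, "tes"] + p.body_offset + 100)
    genes["length"] = (genes["tss"] - genes["tes"]).abs() + 1

    base_rate = np.exp(rng.normal(p.body_rate_meanlog, p.body_rate_sdlog, m))
    base_pause = np.exp(rng.normal(p.pause_meanlog, p.pause_sdlog, m))
    genes["baseline_rate"] = base_rate
    genes["baseline_pause"] = base_pause

    prog_idx = genes["program"].to_numpy() - 1
    percell_rate = pd.DataFrame(
        base_rate[:, None] * ARCHETYPES[prog_idx], index=genes.index, columns=STAGES)
    pause_strength = pd.DataFrame(
        base_pause[:, None] * PAUSE_PROFILES[prog_idx], index=genes.index,
        columns=STAGES)

    dsb_rate = _plant_dsb_rates(pause_strength["SG"], p, rng)

    mito = rng.choice(genes.index[genes["biotype"] == "protein_coding"],
                      size=min(p.n_mito_genes, m), replace=False).tolist()
    non_mito = genes.index.difference(mito)
    eff_a = rng.choice(non_mito, size=min(p.n_effect_genes, len(non_mito)),
                       replace=False)
    # koB shares half its targets with koA (for overlap statistics)
    half = len(eff_a) // 2
    rest = non_mito.difference(eff_a)
    eff_b = np.concatenate([
        eff_a[:half],
        rng.choice(rest, size=min(len(eff_a) - half, len(rest)), replace=False),
    ])
    effect_genes = {"koA": sorted(map(str, eff_a)), "koB": sorted(map(str, eff_b))}

    depths = {}
    for stage in STAGES:
        for r in range(1, p.n_reps + 1):
            depths[f"{stage}_{r}"] = float(np.exp(rng.normal(0, p.depth_sdlog)))

    truth = SynthTruth(params=p, genes=genes, percell_rate=percell_rate,
                       pause_strength=pause_strength, dsb_rate=dsb_rate,
                       mito_genes=sorted(map(str, mito)),
                       effect_genes=effect_genes, sample_depth=depths)
    return truth.gene_models(annotated=True), truth


def _empty_truth(p: SimulationParams) -> SynthTruth:
    empty = pd.DataFrame()
    return SynthTruth(params=p, genes=empty, percell_rate=empty,
                      pause_strength=empty, dsb_rate=pd.Series(dtype=float),
                      mito_genes=[], effect_genes={}, sample_depth={})


def _plant_dsb_rates(pause_sg: pd.Series, p: SimulationParams,
                     rng: np.random.Generator) -> pd.Series:
    """DSB rate as a noisy monotone function of SG pause strength with a
    target Spearman correlation via a Gaussian rank copula."""
    n = len(pause_sg)
    if n == 0:
        return pd.Series(dtype=float)
    # bivariate-normal correlation giving Spearman rho*
    r = 2.0 * np.sin(np.pi * p.dsb_rho / 6.0)
    ranks = pause_sg.rank(method="average").to_numpy()
    from scipy.stats import norm
    z_pause = norm.ppf(ranks / (n + 1))
    z = r * z_pause + np.sqrt(1 - r**2) * rng.standard_normal(n)
    raw = np.exp(0.8 * z)
    rate = p.dsb_mean_reads * raw / raw.mean()
    return pd.Series(rate, index=pause_sg.index, name="dsb_rate")


# ---------------------------------------------------------------------------
# PRO-seq
# ---------------------------------------------------------------------------

def simulate_proseq(truth: SynthTruth, stage: str, replicate: int, seed: int = 0
                    ) -> Tuple[Dict[str, SignalTrack], Dict[str, SignalTrack],
                               int, int]:
    """One PRO-seq sample: per-strand 3' and 5' tracks plus spike/ref reads.

    Promoter (paused) reads fall uniformly on TSS+20..TSS+60 (3' ends) with
    their 5' ends exactly at the true TSS; body reads fall uniformly on
    TSS+250..TES.  Expected per-cell counts are ploidy-compensating by
    construction: per-copy rate = per-cell rate / ploidy, so flat-profile
    genes double their per-copy output in haploid RS.
    """
    p = truth.params
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(seed)
    sample = f"{stage}_{replicate}"
    depth = truth.sample_depth.get(sample, 1.0)

    three = {s: SignalTrack(strand=s, end_type="three_prime") for s in "+-"}
    five = {s: SignalTrack(strand=s, end_type="five_prime") for s in "+-"}
    total_reads = 0
    genes = truth.genes
    rep_noise = np.exp(rng.normal(0, p.rep_noise_sd, len(genes)))
    pause_mu = truth.pause_strength[stage].to_numpy() * depth * rep_noise
    body_mu = (truth.percell_rate[stage].to_numpy()
               * (genes["length"].to_numpy() - p.body_offset).clip(min=0) / 1000.0
               * depth * rep_noise)

    n_pause = rng.poisson(pause_mu)
    n_body = rng.poisson(body_mu)
    for i, (gid, row) in enumerate(genes.iterrows()):
        strand = row["strand"]
        sign = 1 if strand == "+" else -1
        t0 = int(row["true_tss"])
        if n_pause[i] > 0:
            offs = rng.integers(p.pause_offset_lo, p.pause_offset_hi + 1,
                                size=n_pause[i])
            three[strand].add_positions(row["chrom"], t0 + sign * offs)
            five[strand].add_positions(row["chrom"],
                                       np.full(n_pause[i], t0, dtype=np.int64))
        if n_body[i] > 0:
            span = int(abs(row["tes"] - t0)) - p.body_offset
            offs = rng.integers(p.body_offset, p.body_offset + span + 1,
                                size=n_body[i])
            three[strand].add_positions(row["chrom"], t0 + sign * offs)
            five[strand].add_positions(row["chrom"],
                                       np.full(n_body[i], t0, dtype=np.int64))
        total_reads += int(n_pause[i] + n_body[i])

    spike_reads = int(rng.poisson(p.spike_reads_base * depth))
    return three, five, spike_reads, total_reads


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def simulate_rnaseq_counts(truth: SynthTruth, stages: Sequence[str] = STAGES,
                           n_reps: int | None = None, seed: int = 0
                           ) -> CountMatrix:
    """Bulk RNA-seq counts: NB per gene with mean proportional to per-cell
    RNA (ploidy x per-copy rate x length), plus stage-independent
    ERCC-like spike rows and a sample-metadata table."""
    p = truth.params
    n_reps = p.n_reps if n_reps is None else n_reps
    rng = np.random.default_rng(seed)
    genes = truth.genes
    samples, cols, meta = [], {}, []
    alpha = p.dispersion
    ercc_levels = np.exp(rng.normal(np.log(200.0), 1.0, p.n_spike_rows))
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        for rep in range(1, n_reps + 1):
            sample = f"{stage}_{rep}"
            depth = float(np.exp(rng.normal(0, p.depth_sdlog)))
            percell = (truth.percell_rate[stage].to_numpy()
                       * genes["length"].to_numpy() / 1000.0) if len(genes) else np.empty(0)
            mu_genes = p.rna_scale * percell * depth \
                * np.exp(rng.normal(0, p.rep_noise_sd, len(genes)))
            mu_spike = ercc_levels * depth
            mu = np.concatenate([mu_genes, mu_spike])
            counts = _nb_draw(rng, mu, alpha)
            cols[sample] = counts
            ref = int(counts[:len(genes)].sum())
            spk = int(counts[len(genes):].sum())
            meta.append({"sample": sample, "stage": stage, "genotype": "wt",
                         "replicate": rep, "ploidy": PLOIDY[stage],
                         "spike_reads": spk, "ref_reads": ref})
            samples.append(sample)
    index = list(genes.index) + [f"ERCC-{i:05d}" for i in range(p.n_spike_rows)]
    counts_df = pd.DataFrame(cols, index=pd.Index(index, name="gene_id"))
    return CountMatrix(counts_df, pd.DataFrame(meta))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if len(mu) == 0:
        return np.zeros(0, dtype=np.int64)
    if alpha <= 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, np.maximum(mu, 1e-12) / shape)
    return rng.poisson(lam)


def spike_gene_split(cm: CountMatrix) -> Tuple[CountMatrix, CountMatrix]:
    """Split a counts table into (genes, spike rows) by the ERCC- prefix."""
    is_spike = cm.counts.index.str.startswith("ERCC-")
    return (CountMatrix(cm.counts.loc[~is_spike], cm.metadata),
            CountMatrix(cm.counts.loc[is_spike], cm.metadata))


# ---------------------------------------------------------------------------
# Single cell
# ---------------------------------------------------------------------------

def simulate_sc_counts(truth: SynthTruth,
                       genotypes: Sequence[str] | None = None,
                       cells_per_sample: int = 120, seed: int = 0) -> ad.AnnData:
    """Cells x genes counts with planted QC failures and knockout effects.

    Per-cell library sizes are lognormal; a designated mitochondrial gene
    subset carries a few percent of each library (boosted in planted
    high-mito cells); planted low-library cells fail the detected-genes
    threshold.  Knockout genotypes down-shift their designated gene subset
    by ``sc_effect_log2``.
    """
    p = truth.params
    rng = np.random.default_rng(seed)
    genes = truth.genes
    gene_ids = list(genes.index)
    n_genes = len(gene_ids)
    if genotypes is None:
        genotypes = list(p.genotype_samples)
    base = truth.percell_rate["SG"].to_numpy() * genes["length"].to_numpy() / 1000.0
    base = base + base.mean() * 0.06  # expression floor: every gene detectable
    mito_mask = pd.Index(gene_ids).isin(truth.mito_genes)

    obs_rows, X_rows = [], []
    for geno in genotypes:
        n_samp = p.genotype_samples.get(geno, 1)
        eff = np.zeros(n_genes)
        if geno in truth.effect_genes:
            eff_mask = pd.Index(gene_ids).isin(truth.effect_genes[geno])
            eff = np.where(eff_mask, p.sc_effect_log2, 0.0)
        rel = base * np.power(2.0, eff)
        for s in range(1, n_samp + 1):
            sample = f"{geno}_{s}"
            for c in range(cells_per_sample):
                u = rng.random()
                if u < p.sc_fail_low_frac:
                    fail = "low_genes"
                elif u < p.sc_fail_low_frac + p.sc_fail_mito_frac:
                    fail = "high_mito"
                else:
                    fail = "none"
                lib = float(np.exp(rng.normal(p.sc_lib_meanlog, p.sc_lib_sdlog)))
                if fail == "low_genes":
                    lib *= p.sc_fail_lib_scale
                mito_frac = (p.sc_mito_frac_fail if fail == "high_mito"
                             else p.sc_mito_frac_normal)
                w = np.where(mito_mask, 0.0, rel)
                w = w / w.sum() * (1.0 - mito_frac)
                w[mito_mask] = mito_frac / max(mito_mask.sum(), 1)
                counts = rng.poisson(lib * w)
                X_rows.append(counts)
                cell_type = "SG" if rng.random() < 0.5 else "early_SC"
                obs_rows.append({
                    "barcode": f"{sample}_c{c:04d}", "genotype": geno,
                    "sample": sample, "cell_type": cell_type,
                    "planted_fail": fail,
                })
    obs = pd.DataFrame(obs_rows)
    if len(obs):
        obs = obs.set_index("barcode")
        X = sp.csr_matrix(np.vstack(X_rows).astype(np.int64))
    else:
        obs = pd.DataFrame(index=pd.Index([], name="barcode"))
        X = sp.csr_matrix((0, n_genes), dtype=np.int64)
    return ad.AnnData(X=X, obs=obs,
                      var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")))


# ---------------------------------------------------------------------------
# DSB track
# ---------------------------------------------------------------------------

def simulate_spo11(truth: SynthTruth, seed: int = 0) -> SignalTrack:
    """Strandless DSB read track: per-promoter Poisson reads placed around
    a point ~100 nt downstream of the true TSS (strand-aware offset)."""
    p = truth.params
    rng = np.random.default_rng(seed)
    track = SignalTrack(strand="+", end_type="generic")
    if len(truth.genes) == 0:
        return track
    n_reads = rng.poisson(truth.dsb_rate.to_numpy())
    for i, (gid, row) in enumerate(truth.genes.iterrows()):
        if n_reads[i] == 0:
            continue
        sign = 1 if row["strand"] == "+" else -1
        offs = np.round(rng.normal(p.dsb_offset, p.dsb_sd, n_reads[i])).astype(int)
        pos = int(row["true_tss"]) + sign * offs
        track.add_positions(row["chrom"], pos[pos >= 0])
    return track
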