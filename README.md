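# pausekit

Analysis pipeline for promoter-proximal RNA polymerase II pausing across
staged male germ cells, built around nascent-RNA sequencing (PRO-seq-style
single-nucleotide 3'/5'-end coverage), spike-in normalized RNA-seq and
single-cell RNA-seq, and meiotic double-strand-break (DSB) maps.

## The problem

Spermatogenesis proceeds through mitotic spermatogonia (SG, diploid),
meiotic spermatocytes (SC) and post-meiotic haploid round spermatids (RS).
Comparing transcription across these stages raises three quantitative
problems that this package addresses end to end:

1. **Absolute normalization.** Per-cell RNA content and genome copy number
   both change across stages, so counts must be anchored to spike-ins and
   corrected for ploidy. RNA-seq size factors are
   `ref_reads / spike_reads`, halved for haploid samples (so normalized
   signal reads out per genome copy); nascent tracks are rescaled to the
   lowest-spike sample. A consequence of the haploid correction is the
   *dosage compensation* readout: genes whose per-cell RNA is preserved
   through meiosis must double their per-copy transcription, and the
   pipeline measures this as the median gene-body log2 fold change of
   "unchanged" genes, reported with its linear fold `2^median`.
2. **Where is the polymerase?** Pausing is quantified by strand-aware
   window sums: promoter `[TSS, TSS+150)` versus gene body
   `[TSS+250, TES]`, after TSSs are re-aligned to the maximal nascent
   5'-end position within a 1 kb window (a gene is "active" with >= 8
   pooled 5' reads). Expression programs are k-means clusters (k = 6,
   Euclidean) of fraction-of-maximum expression profiles.
3. **Pausing vs DSB formation.** SPO11-oligo-like DSB reads are summed in
   +/-500 nt TSS flanks over promoters with >= 5 reads, stratified into
   signal quartiles, and correlated with promoter signal (Spearman).

Because the deposited datasets are not shipped, the package includes a
first-class synthetic-data generator that plants every structure the
analysis assumes (pause peaks 20-60 nt downstream of the TSS, ploidy and
spike-in effects, expression archetypes, knockout effects, QC failure
modes, TSS-proximal DSB hotspots with a target rank correlation), with
ground-truth tables for parameter-recovery tests. See `docs/methods.md`.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
dataset (2,000 genes, 3 stages x 3 replicates, ~15 s total) and write
tables under `results/synthetic_run/results/`:

```bash
python analysis/01_simulate.py
python analysis/02_normalize.py
python analysis/03_refine_tss.py
python analysis/04_quantify.py
python analysis/05_differential.py
python analysis/06_cluster.py
python analysis/07_single_cell.py
python analysis/08_dsb.py
```

Selected output (seed 1):

```
refined TSS equals planted TSS for 2000/2000 active genes
metagene peak at 20..40 nt downstream of the TSS — the promoter-proximal pause
unchanged genes: median 0.75 log2 = 1.68-fold per-copy increase in haploid cells
clustered 1230 DE genes into 6 programs: sizes {1: 333, 2: 60, ..., 6: 387}
late (RS-peaking) program: cluster 6, 19.1% lncRNA
30.0 of 59.0 koA-down genes are also down in koB (hypergeometric p = 1.39e-33)
Spearman rho (promoter signal vs DSB sums): 0.336 over n = 1814
DSB medians decrease monotonically Q1->Q4: True
```

Reading the numbers: TSS refinement recovers every planted start position;
the nascent-3'-end composite peaks in the 20-40 nt bin downstream of the
TSS, the expected pause position; RNA-status-"unchanged" genes show a
1.68-fold per-copy increase in haploids (the truly flat-profile cohort
sits at the planted 2.0-fold; the status group is diluted by genes whose
changes go undetected); and DSB signal tracks promoter signal both as a
rank correlation and across quartiles.

The same stages are available as a CLI
(`pausekit --out-dir RUN --seed N simulate|normalize|refine-tss|quantify|de|cluster|sc|metagene|dsb|enrich`).

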