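"""End-to-end pipeline stages over an on-disk run directory.

Each function reads the formats the simulator writes (bedGraph, BED6, TSV,
MTX, FASTA), runs one analysis stage, writes its tables under
``<run>/results`` and returns them.  The numbered scripts in ``analysis/``
and the ``pausekit`` CLI are thin wrappers around these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import dsb as dsb_mod
from .annotation import GeneModel, read_annotation, write_annotation
from .clusters import (ClusterAssignment, biotype_composition, divergent_pairs,
                       kmeans_cluster, length_comparison, overlap_test,
                       pwm_scan, read_pwm, representation_score, write_pwm, PWM)
from .config import RunConfig
from .counts import (CountMatrix, read_counts_tsv, read_mtx_counts,
                     write_counts_tsv, write_mtx_counts)
from .differential import (classify_status, dosage_statistic, nb_de,
                           pseudobulk, pseudobulk_de, sc_qc)
from .normalization import (SpikeFactor, factors_table, normalize_to_min_spike,
                            promoter_sums, proseq_size_factors, replicate_qc,
                            spike_factor)
from .quantify import (metagene, rank_by_signal, relative_matrix,
                       window_signal_table)
from .refine import refine_all
from .simulate import (PLOIDY, STAGES, SimulationParams, SynthTruth,
                       simulate_annotation, simulate_proseq,
                       simulate_rnaseq_counts, simulate_sc_counts,
                       simulate_spo11, spike_gene_split)
from .tracks import SignalTrack, pool_tracks, read_bedgraph, write_bedgraph

STRAND_NAME = {"+": "plus", "-": "minus"}
NAME_STRAND = {v: k for k, v in STRAND_NAME.items()}


# ---------------------------------------------------------------------------
# Simulation -> run directory
# ---------------------------------------------------------------------------

def run_simulate(out_dir, params: SimulationParams | None = None,
                 seed: int = 0) -> SynthTruth:
    """Generate a full synthetic dataset on disk, with truth tables."""
    p = params or SimulationParams()
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    (out / "proseq").mkdir(exist_ok=True)
    (out / "rnaseq").mkdir(exist_ok=True)
    (out / "sc").mkdir(exist_ok=True)

    rng = np.random.default_rng(seed)
    models, truth = simulate_annotation(p, seed=seed)
    write_annotation(models, out / "annotation.bed")

    meta = []
    for stage in STAGES:
        for rep in range(1, p.n_reps + 1):
            sample = f"{stage}_{rep}"
            sub_seed = int(rng.integers(0, 2**31 - 1))
            three, five, spike_reads, ref_reads = simulate_proseq(
                truth, stage, rep, seed=sub_seed)
            for strand in "+-":
                write_bedgraph(three[strand],
                               out / "proseq" / f"{sample}.3p.{STRAND_NAME[strand]}.bedgraph")
                write_bedgraph(five[strand],
                               out / "proseq" / f"{sample}.5p.{STRAND_NAME[strand]}.bedgraph")
            meta.append({"sample": sample, "stage": stage, "genotype": "wt",
                         "replicate": rep, "ploidy": PLOIDY[stage],
                         "spike_reads": spike_reads, "ref_reads": ref_reads})
    pd.DataFrame(meta).to_csv(out / "proseq" / "samples.tsv", sep="\t", index=False)

    cm = simulate_rnaseq_counts(truth, seed=int(rng.integers(0, 2**31 - 1)))
    write_counts_tsv(cm, out / "rnaseq" / "counts.tsv", out / "rnaseq" / "samples.tsv")

    adata = simulate_sc_counts(truth, seed=int(rng.integers(0, 2**31 - 1)))
    write_mtx_counts(adata, out / "sc" / "matrix.mtx", out / "sc" / "features.tsv",
                     out / "sc" / "barcodes.tsv")
    adata.obs.to_csv(out / "sc" / "cells.tsv", sep="\t")

    spo = simulate_spo11(truth, seed=int(rng.integers(0, 2**31 - 1)))
    write_bedgraph(spo, out / "spo11.bedgraph")

    _write_promoters(out, truth, rng)

    # truth tables
    truth.genes.to_csv(out / "truth" / "genes.tsv", sep="\t")
    truth.percell_rate.to_csv(out / "truth" / "percell_rate.tsv", sep="\t")
    truth.pause_strength.to_csv(out / "truth" / "pause_strength.tsv", sep="\t")
    truth.dsb_rate.to_frame().to_csv(out / "truth" / "dsb_rate.tsv", sep="\t")
    pd.Series(truth.mito_genes).to_csv(out / "truth" / "mito_genes.txt",
                                       index=False, header=False)
    eff = pd.DataFrame([{"genotype": g, "gene_id": gid}
                        for g, gids in truth.effect_genes.items() for gid in gids])
    eff.to_csv(out / "truth" / "effect_genes.tsv", sep="\t", index=False)
    return truth


TATA_CONSENSUS = "TATAAA"


def _write_promoters(out: Path, truth: SynthTruth, rng: np.random.Generator,
                     upstream: int = 100, tata_fraction: float = 0.3) -> None:
    """Random promoter sequences (100 nt upstream of the TSS) with the TATA
    consensus planted ~30 nt upstream in a known subset; plus a synthetic
    TATA-like PWM for scanning."""
    has_tata = {}
    with open(out / "promoters.fasta", "w") as fh:
        for gid in truth.genes.index:
            seq = "".join(rng.choice(list("ACGT"), size=upstream))
            planted = bool(rng.random() < tata_fraction)
            if planted:
                pos = upstream - 30 - len(TATA_CONSENSUS)
                seq = seq[:pos] + TATA_CONSENSUS + seq[pos + len(TATA_CONSENSUS):]
            has_tata[gid] = planted
            fh.write(f">{gid}\n{seq}\n")
    pd.Series(has_tata, name="has_tata").to_csv(out / "truth" / "has_tata.tsv",
                                                sep="\t")
    write_pwm(synthetic_tata_pwm(), out / "motif.txt")


def synthetic_tata_pwm() -> PWM:
    """A synthetic TATA-box-like PWM (strongly favouring TATAAA)."""
    probs = []
    for base in TATA_CONSENSUS:
        row = np.full(4, 0.04)
        row["ACGT".index(base)] = 0.88
        probs.append(row)
    return PWM(probs=np.array(probs), name="synthetic_TATA")


# ---------------------------------------------------------------------------
# Loading a run directory
# ---------------------------------------------------------------------------

@dataclass
class ProSeqData:
    samples: pd.DataFrame                 # sample metadata incl. spike/ref
    three: Dict[str, Dict[str, SignalTrack]]   # sample -> strand -> 3' track
    five: Dict[str, Dict[str, SignalTrack]]


def load_proseq(run_dir) -> ProSeqData:
    run = Path(run_dir)
    samples = pd.read_csv(run / "proseq" / "samples.tsv", sep="\t")
    three, five = {}, {}
    for sample in samples["sample"]:
        three[sample] = {
            s: read_bedgraph(run / "proseq" / f"{sample}.3p.{STRAND_NAME[s]}.bedgraph",
                             strand=s, end_type="three_prime") for s in "+-"}
        five[sample] = {
            s: read_bedgraph(run / "proseq" / f"{sample}.5p.{STRAND_NAME[s]}.bedgraph",
                             strand=s, end_type="five_prime") for s in "+-"}
    return ProSeqData(samples=samples, three=three, five=five)


def load_annotation(run_dir, refined: bool = False) -> List[GeneModel]:
    run = Path(run_dir)
    path = run / ("results/annotation_refined.bed" if refined else "annotation.bed")
    return read_annotation(path, dialect="bed6")


def results_dir(run_dir) -> Path:
    out = Path(run_dir) / "results"
    out.mkdir(exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# Stage drivers
# ---------------------------------------------------------------------------

def run_normalize(run_dir, cfg: RunConfig | None = None) -> Dict[str, pd.DataFrame]:
    """Spike factors (RNA: ref/spike with ploidy halving; PRO: to-lowest-
    spike track scales) and replicate QC on promoter sums."""
    cfg = cfg or RunConfig()
    run = Path(run_dir)
    pro = load_proseq(run)
    genes = load_annotation(run)

    factors = [spike_factor(r.ref_reads, r.spike_reads, r.ploidy, r.sample)
               for r in pro.samples.itertuples()]
    scales = normalize_to_min_spike(factors)
    ftab = factors_table(factors, scales)

    qc_frames = []
    for stage in pro.samples["stage"].unique():
        reps = pro.samples.loc[pro.samples["stage"] == stage, "sample"]
        tracks = {s: pool_tracks([pro.three[s]["+"], _flip(pro.three[s]["-"])])
                  for s in reps}
        qc = replicate_qc(tracks, genes, window=cfg.promoter_window_len)
        qc.insert(0, "stage", stage)
        qc_frames.append(qc)
    qc_all = pd.concat(qc_frames, ignore_index=True)

    out = results_dir(run)
    ftab.to_csv(out / "spike_factors.tsv", sep="\t", index=False)
    qc_all.to_csv(out / "replicate_qc.tsv", sep="\t", index=False)
    return {"factors": ftab, "replicate_qc": qc_all}


def _flip(track: SignalTrack) -> SignalTrack:
    """Same data re-labelled to the + strand (for strand-pooled promoter QC)."""
    out = SignalTrack(strand="+", end_type=track.end_type)
    out.data = {c: dict(pm) for c, pm in track.data.items()}
    return out


def run_refine(run_dir, cfg: RunConfig | None = None
               ) -> Tuple[List[GeneModel], pd.DataFrame]:
    """Pool unnormalized 5' tracks across all samples and refine TSSs."""
    cfg = cfg or RunConfig()
    run = Path(run_dir)
    pro = load_proseq(run)
    genes = load_annotation(run)
    five = {s: [pro.five[sample][s] for sample in pro.five] for s in "+-"}
    refined, summary = refine_all(genes, five, min_reads=cfg.tss_min_reads,
                                  window=cfg.tss_search_window)
    out = results_dir(run)
    write_annotation(refined, out / "annotation_refined.bed")
    active = [g for g in refined if g.active]
    write_annotation(active, out / "annotation_active.bed")
    summary.to_csv(out / "refine_summary.tsv", sep="\t", index=False)
    return refined, summary


def run_quantify(run_dir, cfg: RunConfig | None = None) -> Dict[str, pd.DataFrame]:
    """Per-sample promoter/body window tables on the active refined
    annotation, plus per-stage pooled promoter/body matrices and a
    promoter-region metagene."""
    cfg = cfg or RunConfig()
    run = Path(run_dir)
    pro = load_proseq(run)
    active = read_annotation(results_dir(run) / "annotation_active.bed")

    per_sample: Dict[str, pd.DataFrame] = {}
    for sample in pro.three:
        tabs = [window_signal_table(pro.three[sample][s],
                                    [g for g in active if g.strand == s],
                                    promoter_len=cfg.promoter_window_len,
                                    body_offset=cfg.body_offset)
                for s in "+-"]
        per_sample[sample] = pd.concat(tabs)

    stage_of = dict(zip(pro.samples["sample"], pro.samples["stage"]))
    stages = list(dict.fromkeys(stage_of.values()))
    prom = pd.DataFrame({st: sum(per_sample[s]["promoter_reads"]
                                 for s in per_sample if stage_of[s] == st)
                         for st in stages})
    body = pd.DataFrame({st: sum(per_sample[s]["body_reads"]
                                 for s in per_sample if stage_of[s] == st)
                         for st in stages})

    pooled_plus = pool_tracks([pro.three[s]["+"] for s in pro.three])
    tss_plus = [(g.chrom, g.tss, g.strand) for g in active if g.strand == "+"]
    profile = metagene(pooled_plus, tss_plus, bin_size=20, range_nt=(-500, 1500))

    out = results_dir(run)
    long = pd.concat([t.assign(sample=s) for s, t in per_sample.items()])
    long.to_csv(out / "window_signal.tsv", sep="\t")
    prom.to_csv(out / "promoter_by_stage.tsv", sep="\t")
    body.to_csv(out / "body_by_stage.tsv", sep="\t")
    profile.to_frame().to_csv(out / "metagene_proseq.tsv", sep="\t", index=False)
    return {"per_sample": long, "promoter_by_stage": prom,
            "body_by_stage": body, "metagene": profile.to_frame()}


def _rna_size_factors(md: pd.DataFrame, ploidy_correct: bool) -> pd.Series:
    return pd.Series({
        r.sample: spike_factor(r.ref_reads, r.spike_reads,
                               r.ploidy if ploidy_correct else 2, r.sample).factor
        for r in md.itertuples()})


def run_de(run_dir, cfg: RunConfig | None = None) -> Dict[str, pd.DataFrame]:
    """Bulk DE: RNA-seq stage contrasts with enforced spike factors
    (per-cell), nascent body-count contrasts (per-copy), and the
    dosage-compensation statistic for the meiotic exit (SC vs RS)."""
    cfg = cfg or RunConfig()
    run = Path(run_dir)
    cm = read_counts_tsv(run / "rnaseq" / "counts.tsv", run / "rnaseq" / "samples.tsv")
    genes_cm, _spikes = spike_gene_split(cm)
    md = genes_cm.metadata

    sf_cell = _rna_size_factors(md, ploidy_correct=False)
    results: Dict[str, pd.DataFrame] = {}
    contrasts = [("SG", "SC"), ("SC", "RS")]
    for a, b in contrasts:
        ga = md.loc[md["stage"] == a, "sample"].tolist()
        gb = md.loc[md["stage"] == b, "sample"].tolist()
        de = classify_status(nb_de(genes_cm, sf_cell, ga, gb),
                             padj_thr=cfg.de_padj_bulk, fc_thr=cfg.de_fc_bulk)
        results[f"rna_{a}_vs_{b}"] = de

    # nascent body counts per sample (from quantify) with per-copy factors
    ws = pd.read_csv(results_dir(run) / "window_signal.tsv", sep="\t")
    body = ws.pivot_table(index="gene_id", columns="sample", values="body_reads")
    body = body.dropna().round().astype(int)
    pro_meta = pd.read_csv(run / "proseq" / "samples.tsv", sep="\t")
    pro_factors = [spike_factor(r.ref_reads, r.spike_reads, r.ploidy, r.sample)
                   for r in pro_meta.itertuples()]
    sf_copy = proseq_size_factors(pro_factors)
    stage_of = dict(zip(pro_meta["sample"], pro_meta["stage"]))
    pro_cm = CountMatrix(body)
    for a, b in contrasts:
        ga = [s for s in body.columns if stage_of[s] == a]
        gb = [s for s in body.columns if stage_of[s] == b]
        de = classify_status(nb_de(pro_cm, sf_copy[body.columns], ga, gb),
                             padj_thr=cfg.de_padj_bulk, fc_thr=cfg.de_fc_bulk)
        results[f"pro_{a}_vs_{b}"] = de

    dosage = dosage_statistic(results["rna_SC_vs_RS"]["status"],
                              results["pro_SC_vs_RS"]["log2fc"])
    results["dosage"] = dosage

    out = results_dir(run)
    for name, df in results.items():
        df.to_csv(out / f"de_{name}.tsv", sep="\t")
    return results


def run_cluster(run_dir, cfg: RunConfig | None = None) -> Dict[str, object]:
    """Expression programs from relative RNA levels of DE genes, plus
    biotype composition, length contrasts, divergent pairs and promoter
    motif content."""
    cfg = cfg or RunConfig()
    run = Path(run_dir)
    out = results_dir(run)
    cm = read_counts_tsv(run / "rnaseq" / "counts.tsv", run / "rnaseq" / "samples.tsv")
    genes_cm, _ = spike_gene_split(cm)
    md = genes_cm.metadata
    sf = _rna_size_factors(md, ploidy_correct=False)
    norm = genes_cm.counts.div(sf, axis=1)
    stages = list(dict.fromkeys(md["stage"]))
    stage_mean = pd.DataFrame({
        st: norm[md.loc[md["stage"] == st, "sample"]].mean(axis=1) for st in stages})

    # genes DE in any stage contrast, with defined adjusted p throughout
    de_any = set()
    tested = None
    for a, b in (("SG", "SC"), ("SC", "RS")):
        de = pd.read_csv(out / f"de_rna_{a}_vs_{b}.tsv", sep="\t", index_col=0)
        de_any |= set(de.index[de["status"].isin(["up", "down"])])
        ok = set(de.index[de["padj"].notna()])
        tested = ok if tested is None else (tested & ok)
    keep = sorted((de_any & tested) if tested else de_any)
    relmat = relative_matrix(stage_mean.loc[keep])
    assignment = kmeans_cluster(relmat, k=cfg.kmeans_k, seed=cfg.seed)

    annot = read_annotation(run / "annotation.bed")
    comp = biotype_composition(assignment, annot)
    late = assignment.centroids.idxmax(axis=1).eq(stages[-1])
    focal = int(assignment.centroids.index[late][0]) if late.any() else cfg.kmeans_k
    lengths = length_comparison(assignment, annot, focal_cluster=focal)
    pairs = divergent_pairs(annot, assignment, focal_cluster=focal,
                            max_dist=1000)

    seqs = _read_fasta(run / "promoters.fasta")
    pwm = read_pwm(run / "motif.txt")
    matches, pct = pwm_scan(seqs, pwm, p_thr=0.005)

    assignment.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    assignment.centroids.to_csv(out / "cluster_centroids.tsv", sep="\t")
    comp.to_csv(out / "cluster_biotypes.tsv", sep="\t")
    lengths.to_csv(out / "cluster_lengths.tsv", sep="\t")
    pd.DataFrame(pairs, columns=["mrna", "lncrna"]).to_csv(
        out / "divergent_pairs.tsv", sep="\t", index=False)
    matches.to_csv(out / "pwm_matches.tsv", sep="\t")
    return {"assignment": assignment, "composition": comp, "lengths": lengths,
            "pairs": pairs, "pwm_percent": pct, "focal_cluster": focal,
            "relmat": relmat}


def _read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_sc(run_dir, cfg: RunConfig | None = None) -> Dict[str, object]:
    """Single-cell QC, pseudobulk aggregation and knockout DE with the
    stricter pseudobulk thresholds, plus DE-set overlap statistics."""
    cfg = cfg or RunConfig()
    run = Path(run_dir)
    adata = read_mtx_counts(run / "sc" / "matrix.mtx", run / "sc" / "features.tsv",
                            run / "sc" / "barcodes.tsv")
    obs = pd.read_csv(run / "sc" / "cells.tsv", sep="\t", index_col=0)
    adata.obs = obs.loc[adata.obs_names]
    mito = pd.read_csv(run / "truth" / "mito_genes.txt", header=None)[0].tolist()

    filtered, report = sc_qc(adata, mito)
    cells_by_genotype = filtered.obs["genotype"].value_counts()

    pb = pseudobulk(filtered, "cell_type", ["SG", "early_SC"], "sample")
    de_tables = {}
    for ko in ("koA", "koB"):
        de_tables[ko] = pseudobulk_de(pb, "control", ko,
                                      padj_thr=cfg.de_padj_sc,
                                      lfc_thr=cfg.de_lfc_sc)
    down_a = set(de_tables["koA"].index[de_tables["koA"]["status"] == "down"])
    down_b = set(de_tables["koB"].index[de_tables["koB"]["status"] == "down"])
    n_overlap, p_overlap = overlap_test(down_a, down_b, universe_size=pb.counts.shape[0])

    out = results_dir(run)
    report.to_csv(out / "sc_qc_report.tsv", sep="\t", index=False)
    cells_by_genotype.to_csv(out / "sc_cells_by_genotype.tsv", sep="\t")
    for ko, de in de_tables.items():
        de.to_csv(out / f"de_sc_{ko}_vs_control.tsv", sep="\t")
    overlap = pd.DataFrame([{"n_down_koA": len(down_a), "n_down_koB": len(down_b),
                             "overlap": n_overlap, "hypergeom_p": p_overlap}])
    overlap.to_csv(out / "sc_overlap.tsv", sep="\t", index=False)
    return {"filtered": filtered, "report": report,
            "cells_by_genotype": cells_by_genotype, "de": de_tables,
            "overlap": overlap, "pseudobulk": pb}


def run_dsb(run_dir, cfg: RunConfig | None = None) -> Dict[str, object]:
    """DSB-promoter association: filter, quartiles, flank sums, Spearman
    correlation, quartile rank tests and a DSB metagene."""
    cfg = cfg or RunConfig()
    run = Path(run_dir)
    out = results_dir(run)
    active = read_annotation(out / "annotation_active.bed")
    prom = pd.read_csv(out / "promoter_by_stage.tsv", sep="\t", index_col=0)
    sg_prom = prom["SG"]

    retained = dsb_mod.promoter_filter(sg_prom, min_reads=cfg.quartile_min_reads)
    quartiles = dsb_mod.quartile_stratify(sg_prom.loc[retained])

    spo = read_bedgraph(run / "spo11.bedgraph")
    gmap = {g.gene_id: g for g in active}
    sums = dsb_mod.dsb_promoter_sum(spo, [gmap[g] for g in retained],
                                    flank=cfg.dsb_flank)
    rho, n = dsb_mod.pause_dsb_correlation(sg_prom.loc[retained], sums)
    comparison = dsb_mod.quartile_dsb_comparison(quartiles, sums)

    tss_list = [(g.chrom, g.tss, g.strand) for g in active]
    profile = metagene(spo, tss_list, bin_size=50, range_nt=(-1000, 1000))

    quartiles.to_frame().join(sums).to_csv(out / "dsb_quartiles.tsv", sep="\t")
    pd.DataFrame([{"spearman_rho": rho, "n": n}]).to_csv(
        out / "dsb_correlation.tsv", sep="\t", index=False)
    comparison.to_csv(out / "dsb_quartile_tests.tsv", sep="\t")
    profile.to_frame().to_csv(out / "metagene_spo11.tsv", sep="\t", index=False)
    return {"retained": retained, "quartiles": quartiles, "sums": sums,
            "rho": rho, "n": n, "comparison": comparison,
            "metagene": profile.to_frame()}
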