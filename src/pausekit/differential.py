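"""Differential expression with enforced spike size factors.

The test is a deliberately simple negative-binomial Wald test: counts are
divided by per-sample size factors (spike factors for bulk assays, library
factors for pseudobulk), the NB dispersion is estimated per gene by the
method of moments pooled across the two groups and stabilized toward the
across-gene median, and the log2 fold change between group means (with a
0.5 pseudocount) is tested against a delta-method standard error with a
two-sided normal p-value.  Benjamini-Hochberg adjustment runs over tested
genes only; genes with no counts in either group are "untested", mirroring
the convention of dropping NA-adjusted-p genes from downstream lists.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .counts import CountMatrix

LOG2 = np.log(2.0)
PSEUDOCOUNT = 0.5  # normalized-count pseudocount bounding fold changes


def _group_moments(norm: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Mean and sample variance (ddof=1) of normalized counts for one group."""
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    return mean, var


DISPERSION_PRIOR_WEIGHT = 100.0  # pseudo-observations behind the consensus


def _pooled_dispersion(meanA, varA, nA, meanB, varB, nB) -> np.ndarray:
    """Per-gene MoM NB dispersion pooled across groups, moderated.

    The variance model Var(norm) = mu + alpha*mu^2 is written in normalized
    counts so the test depends on the data only through them; size factors
    enter solely via the normalization step.  Raw per-gene estimates from
    2-4 replicates are far too noisy to plug into a Wald se (their sampling
    error inflates the type-I rate), so each is combined with the across-
    gene mean of the raw (unfloored) estimates, weighted by its degrees of
    freedom against a fixed prior weight; the result is floored at 0.
    """

    def one(mean, var):
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mean) / mean**2
        return np.where(mean > 0, a, np.nan)

    aA, aB = one(meanA, varA), one(meanB, varB)
    w = np.array([nA - 1, nB - 1], dtype=float)
    stacked = np.vstack([aA, aB])
    with np.errstate(invalid="ignore"):
        num = np.nansum(stacked * w[:, None], axis=0)
        den = ((~np.isnan(stacked)) * w[:, None]).sum(axis=0)
    raw = np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)
    finite = raw[np.isfinite(raw)]
    # the unfloored mean is close to unbiased for the consensus dispersion
    prior = max(float(np.mean(finite)), 0.0) if len(finite) else 0.0
    n0 = DISPERSION_PRIOR_WEIGHT
    alpha = np.where(
        np.isfinite(raw),
        (den * np.maximum(raw, 0.0) + n0 * prior) / (den + n0),
        prior,
    )
    return alpha


def nb_de(counts: CountMatrix, size_factors: pd.Series,
          group_a: Sequence[str], group_b: Sequence[str]) -> pd.DataFrame:
    """NB Wald test of group B vs group A with enforced size factors.

    Returns a DataFrame indexed by gene with columns log2fc, se, p, padj,
    status (status is 'untested' for genes with zero counts throughout;
    other labels are assigned later by :func:`classify_status`).
    """
    group_a, group_b = list(group_a), list(group_b)
    for name, grp in (("A", group_a), ("B", group_b)):
        missing = set(grp) - set(counts.samples)
        if missing:
            raise ValueError(f"group {name}: unknown samples {sorted(missing)}")
        if len(grp) < 2:
            raise ValueError(f"group {name}: need >= 2 replicates for a dispersion estimate")
    sf = size_factors.reindex(counts.samples)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")

    mat = counts.counts.to_numpy(dtype=float)
    sf_vec = sf.to_numpy()
    norm = mat / sf_vec[None, :]
    ia = [counts.counts.columns.get_loc(s) for s in group_a]
    ib = [counts.counts.columns.get_loc(s) for s in group_b]
    nA, nB = len(ia), len(ib)
    meanA, varA = _group_moments(norm[:, ia])
    meanB, varB = _group_moments(norm[:, ib])

    alpha = _pooled_dispersion(meanA, varA, nA, meanB, varB, nB)

    c = PSEUDOCOUNT
    log2fc = np.log2(meanB + c) - np.log2(meanA + c)
    # delta-method variance of each group mean under the NB model,
    # evaluated at mean+pseudocount so zero-count groups keep a finite se
    muA, muB = meanA + c, meanB + c
    varMA = (muA + alpha * muA**2) / nA
    varMB = (muB + alpha * muB**2) / nB
    se = np.sqrt(varMA / muA**2 + varMB / muB**2) / LOG2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    untested = (meanA == 0) & (meanB == 0)
    p = np.where(untested, np.nan, p)
    padj = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        padj[tested] = stats.false_discovery_control(p[tested], method="bh")

    out = pd.DataFrame({
        "log2fc": log2fc, "se": se, "p": p, "padj": padj,
    }, index=counts.genes)
    out["status"] = np.where(untested, "untested", "unchanged")
    return out


def classify_status(de: pd.DataFrame, padj_thr: float = 0.05,
                    fc_thr: float = 1.5) -> pd.DataFrame:
    """Label genes up/down/unchanged by adjusted p and linear fold change;
    'untested' passes through."""
    de = de.copy()
    fc = np.power(2.0, de["log2fc"])
    sig = de["padj"] < padj_thr
    status = np.where(sig & (fc > fc_thr), "up",
                      np.where(sig & (fc < 1.0 / fc_thr), "down", "unchanged"))
    de["status"] = np.where(de["status"] == "untested", "untested", status)
    return de


def dosage_statistic(rna_status: pd.Series, body_log2fc: pd.Series) -> pd.DataFrame:
    """Median nascent (gene body) log2 fold change per RNA-status group.

    The headline use is the haploid transition: genes whose per-cell RNA is
    unchanged across meiosis show a ~2-fold rise in per-copy transcription
    (dosage compensation); the statistic is the per-status median log2FC and
    its linear fold 2**median.
    """
    common = rna_status.index.intersection(body_log2fc.index)
    rows = []
    for status in ("up", "unchanged", "down"):
        vals = body_log2fc.loc[common[rna_status.loc[common] == status]].dropna()
        if len(vals) == 0:
            continue
        med = float(np.median(vals))
        rows.append({"status": status, "n": len(vals),
                     "median_log2fc": med, "fold": 2.0 ** med})
    return pd.DataFrame(rows).set_index("status")


# ---------------------------------------------------------------------------
# Single cell: QC, pseudobulk, shrunken DE
# ---------------------------------------------------------------------------

def sc_qc(adata: ad.AnnData, mito_genes: Iterable[str],
          min_genes: int = 1000, max_mito: float = 0.10,
          min_cells: int = 15) -> Tuple[ad.AnnData, pd.DataFrame]:
    """Cell then gene QC with strict thresholds.

    Cells are kept iff detected genes > ``min_genes`` AND mitochondrial
    fraction < ``max_mito``; genes are then kept iff detected in more than
    ``min_cells`` retained cells.  Returns the filtered AnnData and a
    before/after report.
    """
    X = sp.csr_matrix(adata.X)
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_genes = set(mito_genes)
    mito_mask = adata.var_names.isin(mito_genes)
    if mito_mask.sum() == 0:
        import warnings
        warnings.warn("mitochondrial gene set empty; mito filter skipped")
        mito_frac = np.zeros(adata.n_obs)
        keep_cells = detected > min_genes
    else:
        mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
        keep_cells = (detected > min_genes) & (mito_frac < max_mito)

    filtered = adata[keep_cells].copy()
    Xf = sp.csr_matrix(filtered.X)
    gene_cells = np.asarray((Xf > 0).sum(axis=0)).ravel()
    keep_genes = gene_cells > min_cells
    filtered = filtered[:, keep_genes].copy()
    filtered.obs["detected_genes"] = detected[keep_cells]
    filtered.obs["mito_frac"] = mito_frac[keep_cells]

    report = pd.DataFrame({
        "metric": ["cells_before", "cells_after", "genes_before", "genes_after"],
        "value": [adata.n_obs, int(keep_cells.sum()), adata.n_vars,
                  int(keep_genes.sum())],
    })
    return filtered, report


def pseudobulk(adata: ad.AnnData, cell_label_key: str,
               selected_labels: Iterable[str], sample_key: str) -> CountMatrix:
    """Sum single-cell counts to (sample x gene) over selected cell labels."""
    selected = set(selected_labels)
    mask = adata.obs[cell_label_key].isin(selected).to_numpy()
    sub = adata[mask]
    X = sp.csr_matrix(sub.X)
    samples = sub.obs[sample_key].astype(str)
    cols = {}
    for s in pd.unique(samples):
        rows = (samples == s).to_numpy()
        cols[s] = np.asarray(X[rows].sum(axis=0)).ravel().astype(np.int64)
    counts = pd.DataFrame(cols, index=sub.var_names)
    counts.index.name = "gene_id"
    meta_cols = [c for c in (sample_key, "genotype") if c in sub.obs.columns]
    meta = (sub.obs[meta_cols].astype(str).drop_duplicates()
            .rename(columns={sample_key: "sample"}))
    return CountMatrix(counts, meta.reset_index(drop=True))


def library_size_factors(counts: CountMatrix) -> pd.Series:
    """Total-count size factors scaled to geometric mean 1."""
    totals = counts.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("every sample needs nonzero total counts")
    return totals / np.exp(np.log(totals).mean())


def shrink_lfc(log2fc: pd.Series, se: pd.Series,
               prior_var: Optional[float] = None) -> pd.Series:
    """Empirical-Bayes normal shrinkage of log2 fold changes toward 0.

    The prior variance defaults to the across-gene variance of raw lfc in
    excess of the mean squared standard error (clipped at 0); each gene's
    lfc is scaled by prior_var / (prior_var + se^2).  An infinite prior
    leaves the raw lfc untouched.
    """
    if prior_var is None:
        finite = np.isfinite(log2fc) & np.isfinite(se)
        prior_var = max(float(np.var(log2fc[finite])) -
                        float(np.mean(se[finite] ** 2)), 0.0)
    if np.isinf(prior_var):
        return log2fc.copy()
    w = prior_var / (prior_var + se**2)
    return log2fc * w


def pseudobulk_de(counts: CountMatrix, genotype_a: str, genotype_b: str,
                  padj_thr: float = 0.01, lfc_thr: float = 1.0,
                  prior_var: Optional[float] = None) -> pd.DataFrame:
    """Pseudobulk NB Wald test (B vs A) with shrunken-lfc thresholds.

    Significance requires padj < ``padj_thr`` and |shrunken log2fc| >=
    ``lfc_thr``; the shrunken value is reported alongside the raw one.
    """
    meta = counts.metadata
    groups = {g: meta.loc[meta["genotype"] == g, "sample"].tolist()
              for g in (genotype_a, genotype_b)}
    for g, samp in groups.items():
        if not samp:
            raise ValueError(f"genotype {g!r} absent from metadata")
    sf = library_size_factors(counts)
    de = nb_de(counts, sf, groups[genotype_a], groups[genotype_b])
    de["shrunk_log2fc"] = shrink_lfc(de["log2fc"], de["se"], prior_var=prior_var)
    sig = (de["padj"] < padj_thr) & (de["shrunk_log2fc"].abs() >= lfc_thr)
    status = np.where(sig & (de["shrunk_log2fc"] > 0), "up",
                      np.where(sig, "down", "unchanged"))
    de["status"] = np.where(de["status"] == "untested", "untested", status)
    return de
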