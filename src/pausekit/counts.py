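"""Count matrices and their on-disk forms.

Bulk counts are a genes x samples integer table with a sample-metadata
sidecar (stage, genotype, replicate, ploidy, spike reads).  Single-cell
counts use :class:`anndata.AnnData` (cells x genes), read from MatrixMarket
triplets plus barcode/feature lists, the shape droplet pipelines emit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

METADATA_COLUMNS = ["sample", "stage", "genotype", "replicate", "ploidy",
                    "spike_reads", "ref_reads"]


@dataclass
class CountMatrix:
    """Genes x samples counts with aligned per-sample metadata."""

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.metadata.empty:
            missing = set(self.counts.columns) - set(self.metadata["sample"])
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")
            self.metadata = (
                self.metadata.set_index("sample", drop=False)
                .loc[list(self.counts.columns)]
                .reset_index(drop=True)
            )

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.metadata)

    def scaled(self, scales: pd.Series) -> "CountMatrix":
        """Multiply each sample column by its scale (normalization output)."""
        out = self.counts.astype(float).mul(scales.reindex(self.counts.columns), axis=1)
        return CountMatrix(out, self.metadata)


def write_counts_tsv(cm: CountMatrix, counts_path, metadata_path=None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    if metadata_path is not None:
        cm.metadata.to_csv(metadata_path, sep="\t", index=False)


def read_counts_tsv(counts_path, metadata_path=None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    metadata = pd.DataFrame()
    if metadata_path is not None and Path(metadata_path).exists():
        metadata = pd.read_csv(metadata_path, sep="\t")
    return CountMatrix(counts, metadata)


# ---------------------------------------------------------------------------
# MatrixMarket (single-cell)
# ---------------------------------------------------------------------------

def _read_list(path) -> pd.Index:
    with open(path) as fh:
        items = [line.split("\t")[0].strip() for line in fh if line.strip()]
    return pd.Index(items, dtype=str)


def read_mtx_counts(mtx_path, features_path, barcodes_path) -> ad.AnnData:
    """Read an MTX triplet file plus feature/barcode lists into AnnData.

    The matrix on disk is genes x cells (the droplet-pipeline convention);
    the returned AnnData is cells x genes.  Indices out of the declared
    bounds raise.
    """
    mat = scipy.io.mmread(str(mtx_path))
    features = _read_list(features_path)
    barcodes = _read_list(barcodes_path)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    adata = ad.AnnData(
        X=mat.T.tocsr(),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene_id")),
    )
    return adata


def write_mtx_counts(adata: ad.AnnData, mtx_path, features_path, barcodes_path) -> None:
    """Write AnnData (cells x genes) as genes x cells MTX + sidecar lists."""
    mat = sp.coo_matrix(adata.X).astype(np.int64).T
    scipy.io.mmwrite(str(mtx_path), mat, field="integer")
    pd.Series(adata.var_names).to_csv(features_path, sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(barcodes_path, sep="\t", header=False, index=False)
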