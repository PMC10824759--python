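"""Expression programs and their characterization.

Genes are grouped by k-means (k=6, Euclidean) on relative-expression
profiles (fraction of the maximal stage), then characterized: biotype
composition, gene-length contrasts, divergent mRNA-lncRNA pairs, how
strongly DE gene sets concentrate in each program, set-overlap
significance, and core-promoter motif content.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .annotation import GeneModel
from .utils import percent


@dataclass
class ClusterAssignment:
    labels: pd.Series            # gene_id -> 1..k
    centroids: pd.DataFrame      # k x n_stages, rows indexed 1..k
    relmat: pd.DataFrame         # the relative-expression matrix clustered

    @property
    def k(self) -> int:
        return len(self.centroids)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def members(self, cluster: int) -> pd.Index:
        return self.labels.index[self.labels == cluster]


def kmeans_cluster(relmat: pd.DataFrame, k: int = 6, seed: int = 0,
                   n_restarts: int = 25) -> ClusterAssignment:
    """K-means on relative-expression rows; deterministic presentation order.

    Best of ``n_restarts`` by within-cluster sum of squares; labels are then
    renumbered by the stage at which each centroid peaks (earliest-peaking
    first) with descending size breaking ties, so cluster numbering is a
    stable, meaningful ordering rather than an arbitrary fit artifact.
    """
    if k > len(relmat):
        raise ValueError(f"k={k} exceeds {len(relmat)} genes")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(relmat.to_numpy())
    centroids = km.cluster_centers_
    sizes = np.bincount(raw, minlength=k)
    order = sorted(range(k), key=lambda c: (int(np.argmax(centroids[c])), -sizes[c]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[r] for r in raw], index=relmat.index, name="cluster")
    cent = pd.DataFrame(centroids[order], index=pd.RangeIndex(1, k + 1, name="cluster"),
                        columns=relmat.columns)
    return ClusterAssignment(labels=labels, centroids=cent, relmat=relmat)


def biotype_composition(assignment: ClusterAssignment,
                        genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Percent of each cluster's genes per biotype (rows sum to 100)."""
    biomap = {g.gene_id: g.biotype for g in genes}
    df = pd.DataFrame({
        "cluster": assignment.labels.values,
        "biotype": [biomap[g] for g in assignment.labels.index],
    })
    tab = df.groupby(["cluster", "biotype"]).size().unstack(fill_value=0)
    return tab.div(tab.sum(axis=1), axis=0) * 100.0


def length_comparison(assignment: ClusterAssignment, genes: Sequence[GeneModel],
                      focal_cluster: int) -> pd.DataFrame:
    """Two-sided Mann-Whitney U on TSS-TES lengths, focal vs each other
    cluster; exact when the combined sample is small (n <= 20)."""
    lengths = pd.Series({g.gene_id: g.length for g in genes})
    focal = lengths.loc[assignment.members(focal_cluster)]
    rows = []
    for c in sorted(assignment.labels.unique()):
        if c == focal_cluster:
            continue
        other = lengths.loc[assignment.members(c)]
        method = "exact" if len(focal) + len(other) <= 20 else "asymptotic"
        res = stats.mannwhitneyu(focal, other, alternative="two-sided",
                                 method=method)
        rows.append({"cluster": c, "n_focal": len(focal), "n_other": len(other),
                     "median_focal": float(np.median(focal)),
                     "median_other": float(np.median(other)),
                     "p": float(res.pvalue)})
    return pd.DataFrame(rows).set_index("cluster")


def divergent_pairs(genes: Sequence[GeneModel], assignment: ClusterAssignment,
                    focal_cluster: int, max_dist: int = 1000
                    ) -> List[Tuple[str, str]]:
    """(mRNA, lncRNA) pairs in antisense orientation within ``max_dist`` nt
    of each other's TSS, both members of the focal cluster; each lncRNA is
    paired with its nearest qualifying mRNA."""
    members = set(assignment.members(focal_cluster))
    mrnas = [g for g in genes
             if g.biotype == "protein_coding" and g.gene_id in members]
    lncs = [g for g in genes if g.biotype == "lncRNA" and g.gene_id in members]
    pairs = []
    for lnc in lncs:
        best, best_d = None, max_dist + 1
        for m in mrnas:
            if m.chrom != lnc.chrom or m.strand == lnc.strand:
                continue
            d = abs(m.tss - lnc.tss)
            if d <= max_dist and d < best_d:
                best, best_d = m, d
        if best is not None:
            pairs.append((best.gene_id, lnc.gene_id))
    return pairs


def representation_score(de_genes: Set[str], assignment: ClusterAssignment
                         ) -> pd.Series:
    """Per-cluster enrichment of a DE gene set, normalized by cluster size.

    score_c = (|DE in c| / |DE in any cluster|) / (|c| / total clustered);
    a value of 1 means the cluster holds exactly its size-expected share.
    """
    labels = assignment.labels
    de_in_clusters = labels.index.intersection(de_genes)
    if len(de_in_clusters) == 0:
        raise ValueError("DE set shares no genes with the clustering")
    total = len(labels)
    scores = {}
    for c in sorted(labels.unique()):
        members = assignment.members(c)
        prop_de = len(members.intersection(de_genes)) / len(de_in_clusters)
        prop_size = len(members) / total
        scores[c] = prop_de / prop_size
    return pd.Series(scores, name="representation")


def overlap_test(set_a: Set[str], set_b: Set[str], universe_size: int
                 ) -> Tuple[int, float]:
    """Overlap count and upper-tail hypergeometric P(X >= overlap)."""
    if universe_size < len(set_a) or universe_size < len(set_b):
        raise ValueError("universe smaller than a set")
    overlap = len(set_a & set_b)
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(set_a), len(set_b)))
    return overlap, p


# ---------------------------------------------------------------------------
# PWM scanning with exact background p-values
# ---------------------------------------------------------------------------

ALPHABET = "ACGT"


@dataclass
class PWM:
    """Column-stochastic position weight matrix over ACGT."""

    probs: np.ndarray   # length x 4
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be length x 4 over ACGT")
        if (self.probs <= 0).any():
            raise ValueError("PWM has zero-probability cells; apply a pseudocount")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return np.log2(self.probs / bg[None, :])

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


def read_pwm(path) -> PWM:
    """Read a MEME-style text PWM: a MOTIF line then a letter-probability
    matrix block with one row per position (columns A C G T)."""
    name = "motif"
    rows: List[List[float]] = []
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("MOTIF"):
                parts = s.split()
                if len(parts) > 1:
                    name = parts[1]
            elif s.startswith("letter-probability"):
                in_matrix = True
            elif in_matrix and s:
                vals = s.split()
                if len(vals) != 4:
                    break
                rows.append([float(v) for v in vals])
    if not rows:
        raise ValueError(f"no probability matrix found in {path}")
    probs = np.asarray(rows)
    # guard against zero cells with a small pseudocount, renormalized
    probs = probs + 1e-4
    probs /= probs.sum(axis=1, keepdims=True)
    return PWM(probs=probs, name=name)


def write_pwm(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write(f"MOTIF {pwm.name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pwm.length}\n")
        for row in pwm.probs:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def score_distribution(pwm: PWM, background: np.ndarray | None = None
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the log-odds score of a random background word.

    Dynamic program position-by-position over achievable partial sums
    (floats merge exactly because every path adds columns left to right,
    matching how scan scores are computed).  Returns sorted unique scores
    and their upper-tail probabilities P(score >= s).
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    lo = pwm.log_odds(bg)
    dist: Dict[float, float] = {0.0: 1.0}
    for i in range(pwm.length):
        new: Dict[float, float] = {}
        for s, prob in dist.items():
            for j in range(4):
                key = s + lo[i, j]
                new[key] = new.get(key, 0.0) + prob * bg[j]
        dist = new
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    upper = np.cumsum(probs[::-1])[::-1]
    return scores, upper


def pwm_scan(sequences: Dict[str, str], pwm: PWM, p_thr: float = 0.005,
             background: np.ndarray | None = None) -> Tuple[pd.DataFrame, float]:
    """Scan each sequence with the PWM; a hit is an offset whose score has
    exact background p-value <= ``p_thr``.

    Returns (per-gene match table, percent of genes with >= 1 match).
    Sequences shorter than the motif are warned about and scanned as empty.
    """
    if len(sequences) == 0:
        raise ValueError("no sequences to scan")
    lo = pwm.log_odds(background)
    scores_u, upper = score_distribution(pwm, background)
    idx = {b: i for i, b in enumerate(ALPHABET)}
    rows = []
    for name, seq in sequences.items():
        seq = seq.upper()
        n_hits = 0
        best_p = 1.0
        if len(seq) < pwm.length:
            warnings.warn(f"{name}: sequence shorter than motif; skipped")
        else:
            for off in range(len(seq) - pwm.length + 1):
                word = seq[off:off + pwm.length]
                try:
                    s = 0.0
                    for i, b in enumerate(word):
                        s += lo[i, idx[b]]
                except KeyError:
                    continue  # ambiguous base
                # scan scores add columns in the same order as the DP, so the
                # float sum exists exactly in the tabulated score set
                i_s = int(np.searchsorted(scores_u, s, side="left"))
                pval = float(upper[i_s]) if i_s < len(upper) else 0.0
                if pval <= p_thr:
                    n_hits += 1
                best_p = min(best_p, pval)
            rows.append({"gene_id": name, "n_matches": n_hits, "best_p": best_p})
    if not rows:
        raise ValueError("no scannable sequences")
    table = pd.DataFrame(rows).set_index("gene_id")
    pct = percent(int((table["n_matches"] > 0).sum()), len(table))
    return table, pct
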