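"""Gene models and annotation I/O (BED6 and a minimal GTF dialect).

Internal coordinates are 0-based half-open throughout; BED is native and
GTF (1-based closed) is converted at the boundary.  A gene is stored by its
oriented endpoints: ``tss`` is the first transcribed base and ``tes`` the
last, so on the minus strand ``tss > tes``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List

Biotype = str  # {"protein_coding", "lncRNA", "other"}


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    biotype: Biotype = "protein_coding"
    active: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: - strand requires tss > tes")

    @property
    def start(self) -> int:
        """Leftmost genomic base (0-based)."""
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        """One past the rightmost genomic base (half-open end)."""
        return max(self.tss, self.tes) + 1

    @property
    def length(self) -> int:
        """TSS-to-TES span in nt, strand-independent."""
        return abs(self.tes - self.tss) + 1

    def with_tss(self, tss: int, active: bool) -> "GeneModel":
        return replace(self, tss=tss, active=active)


def _check_unique(genes: List[GeneModel]) -> List[GeneModel]:
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def read_annotation(path, dialect: str = "bed6") -> List[GeneModel]:
    """Read gene models from BED6 or a minimal gene-line GTF.

    BED6 is 0-based half-open with strand in column 6; the minimal GTF
    dialect is 1-based closed with feature lines of type ``gene`` carrying a
    ``gene_id`` attribute.  Both map onto the same oriented (tss, tes).
    """
    if dialect not in ("bed6", "gtf_lite"):
        raise ValueError(f"unknown dialect {dialect!r}")
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if dialect == "bed6":
                if len(parts) < 6:
                    raise ValueError(f"line {lineno}: BED6 needs 6 columns")
                chrom, start, end, name, _score, strand = parts[:6]
                start, end = int(start), int(end)
                biotype = parts[6] if len(parts) > 6 else "protein_coding"
            else:
                if len(parts) < 9:
                    raise ValueError(f"line {lineno}: GTF needs 9 columns")
                if parts[2] != "gene":
                    continue
                chrom, strand = parts[0], parts[6]
                start, end = int(parts[3]) - 1, int(parts[4])  # to 0-based half-open
                attrs = parts[8]
                name = _gtf_attr(attrs, "gene_id", lineno)
                biotype = _gtf_attr(attrs, "gene_biotype", lineno, default="protein_coding")
            if strand not in ("+", "-"):
                raise ValueError(f"line {lineno}: strand {strand!r} not in {{+,-}}")
            if strand == "+":
                tss, tes = start, end - 1
            else:
                tss, tes = end - 1, start
            genes.append(
                GeneModel(gene_id=name, chrom=chrom, strand=strand, tss=tss, tes=tes,
                          biotype=biotype)
            )
    return _check_unique(genes)


def _gtf_attr(attrs: str, key: str, lineno: int, default: str | None = None) -> str:
    for field in attrs.split(";"):
        field = field.strip()
        if field.startswith(key):
            return field[len(key):].strip().strip('"')
    if default is not None:
        return default
    raise ValueError(f"line {lineno}: missing attribute {key!r}")


def write_annotation(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as BED6 plus a biotype column (read back losslessly)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{g.biotype}\n"
            )
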