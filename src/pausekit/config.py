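"""Run configuration: the fixed analysis constants, loadable from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    """Analysis-wide constants.

    Window geometry follows the pausing literature: the promoter window
    covers the first 150 nt downstream of the TSS where paused polymerase
    accumulates, and the gene body starts 250 nt downstream so the two
    never overlap.  DE thresholds differ between the bulk contrasts
    (padj < 0.05, fold > 1.5) and the pseudobulk single-cell contrasts
    (padj < 0.01, |shrunken log2FC| >= 1).
    """

    promoter_window_len: int = 150      # nt downstream of TSS
    body_offset: int = 250              # nt; gene body starts at TSS + offset
    tss_search_window: int = 1000       # nt; total width of the 5'-max search
    tss_min_reads: int = 8              # pooled 5' reads required for "active"
    dsb_flank: int = 500                # nt each side of TSS for DSB sums
    quartile_min_reads: int = 5         # promoter reads required before quartiles
    de_padj_bulk: float = 0.05
    de_fc_bulk: float = 1.5
    de_padj_sc: float = 0.01
    de_lfc_sc: float = 1.0
    kmeans_k: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("promoter_window_len", "body_offset", "tss_search_window",
                     "dsb_flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("de_padj_bulk", "de_padj_sc"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
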