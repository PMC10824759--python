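"""Refine annotated TSSs against pooled nascent 5'-end maxima.

A gene is active when the pooled unnormalized 5' reads within the 1 kb
window around its annotated TSS reach 8; its TSS moves to the maximal
5'-count position.
"""

import importlib.util
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from pausekit import workflows

refined, summary = workflows.run_refine(common.RUN_DIR, common.config())
print(summary.to_string(index=False))

truth_genes = pd.read_csv(common.RUN_DIR / "truth" / "genes.tsv", sep="\t",
                          index_col=0)
active = [g for g in refined if g.active]
exact = sum(1 for g in active
            if g.tss == truth_genes.loc[g.gene_id, "true_tss"])
print(f"refined TSS equals planted TSS for {exact}/{len(active)} active genes")
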