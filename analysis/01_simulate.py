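"""Generate the synthetic staged-germ-cell dataset.

Plants three stages (SG, SC, RS) x three replicates of nascent-RNA tracks
with promoter pause peaks, spike-in chimerism and the haploid RS genome,
bulk RNA-seq counts with ERCC-like spike rows, single-cell libraries for
three genotypes with planted QC failures and knockout effects, and a DSB
read track whose intensity tracks SG promoter signal.
"""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from pausekit import workflows

truth = workflows.run_simulate(common.RUN_DIR, seed=common.SEED)
g = truth.genes
print(f"simulated {len(g)} genes on {g['chrom'].iloc[0]} "
      f"({(g['biotype'] == 'protein_coding').sum()} coding, "
      f"{(g['biotype'] == 'lncRNA').sum()} lncRNA)")
print(f"divergent mRNA-lncRNA pairs planted: {(g['paired_with'] != '').sum()}")
print(f"run directory: {common.RUN_DIR}")
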