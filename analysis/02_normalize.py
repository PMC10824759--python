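"""Spike-in normalization factors and replicate agreement.

RNA-seq size factors are reference/spike reads per sample, halved for the
haploid RS stage; nascent tracks are rescaled to the lowest-spike sample.
Replicate agreement is Spearman correlation of per-gene promoter sums
(first 150 bp downstream of each TSS).
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from pausekit import workflows

res = workflows.run_normalize(common.RUN_DIR, common.config())
print(res["factors"].to_string(index=False))
qc = res["replicate_qc"]
print(f"\nreplicate QC: {len(qc)} pairs, "
      f"Spearman rho {qc['spearman_rho'].min():.3f}-{qc['spearman_rho'].max():.3f}")
print("tables: results/spike_factors.tsv, results/replicate_qc.tsv")
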