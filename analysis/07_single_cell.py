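"""Single-cell QC, pseudobulk aggregation and knockout DE.

Cells pass QC with >1000 detected genes and <10% mitochondrial reads;
genes must be detected in >15 retained cells.  Counts are summed to
(sample x gene) over spermatogonia and early meiotic cells, then tested
between genotypes at padj < 0.01 with |shrunken log2FC| >= 1, and the
knockout down-gene sets are compared by a hypergeometric overlap test.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from pausekit import workflows

res = workflows.run_sc(common.RUN_DIR, common.config())
print(res["report"].to_string(index=False))
print("\nretained cells per genotype:")
print(res["cells_by_genotype"].to_string())
for ko, de in res["de"].items():
    n_down = (de["status"] == "down").sum()
    print(f"{ko} vs control: {n_down} genes down at padj<0.01, |lfc|>=1")
ov = res["overlap"].iloc[0]
print(f"\n{ov['overlap']} of {ov['n_down_koA']} koA-down genes are also "
      f"down in koB (hypergeometric p = {ov['hypergeom_p']:.2e})")
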