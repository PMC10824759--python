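"""Stage-contrast differential expression and dosage compensation.

RNA-seq contrasts (SG vs SC, SC vs RS) use enforced spike factors; nascent
body-count contrasts use spike-read factors with the haploid genome-copy
correction, reading out transcription per genome copy.  The dosage
statistic is the median per-copy body log2FC within each RNA status group:
genes whose per-cell RNA is unchanged across meiosis show a ~2-fold
per-copy increase in haploid spermatids.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from pausekit import workflows

res = workflows.run_de(common.RUN_DIR, common.config())
for name in ("rna_SG_vs_SC", "rna_SC_vs_RS"):
    counts = res[name]["status"].value_counts().to_dict()
    print(f"{name}: {counts}")
dosage = res["dosage"]
print("\ndosage statistic (per-copy nascent body log2FC by RNA status):")
print(dosage.round(3).to_string())
unchanged = dosage.loc["unchanged"]
print(f"\nunchanged genes: median {unchanged['median_log2fc']:.2f} log2 "
      f"= {unchanged['fold']:.2f}-fold per-copy increase in haploid cells")
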