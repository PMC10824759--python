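"""Promoter and gene-body window quantification.

Promoter = TSS..TSS+150 (where paused polymerase accumulates); gene body =
TSS+250..TES.  Writes per-sample window tables, per-stage pooled matrices
and a 20-nt-binned metagene around the TSS.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from pausekit import workflows

res = workflows.run_quantify(common.RUN_DIR, common.config())
prom = res["promoter_by_stage"]
print(f"quantified {prom.shape[0]} active genes across stages {list(prom.columns)}")
mg = res["metagene"]
peak = mg.loc[mg["mean"].idxmax()]
print(f"metagene peak at {int(peak['offset'])}..{int(peak['offset']) + 20} nt "
      f"downstream of the TSS (mean {peak['mean']:.2f} reads/TSS/bin) — "
      "the promoter-proximal pause")
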