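"""Expression programs from relative RNA profiles of DE genes.

K-means (k=6, Euclidean) on fraction-of-maximum profiles, then program
characterization: biotype composition, gene-length contrast of the late
program, divergent mRNA-lncRNA pairs within 1 kb, and core-promoter motif
content (exact-p PWM scan of the 100 nt upstream windows).
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from pausekit import workflows

res = workflows.run_cluster(common.RUN_DIR, common.config())
asg = res["assignment"]
print(f"clustered {len(asg.labels)} DE genes into {asg.k} programs: "
      f"sizes {asg.sizes().to_dict()}")
focal = res["focal_cluster"]
comp = res["composition"]
print(f"late (RS-peaking) program: cluster {focal}, "
      f"{comp.loc[focal].get('lncRNA', 0.0):.1f}% lncRNA")
print(f"divergent antisense mRNA-lncRNA pairs in cluster {focal}: "
      f"{len(res['pairs'])}")
print(f"promoters with a motif match at p<=0.005: {res['pwm_percent']:.1f}%")
print(res["lengths"].round(4).to_string())
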