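"""Expression analysis: TMM/log-CPM, per-transition DE, DEG clustering, PCA.

DEGs use the FDR < 0.05 and |log2FC| > 1 rule per consecutive-timepoint
transition; DEG temporal profiles are z-scored and hierarchically clustered
(k = 9 by default, silhouette across k documented alongside).
"""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfgmod = import_module("00_config")

from epidyn import pipeline

res = pipeline.run_expr(
    cfgmod.RUN / "data" / "expression_counts.tsv", cfgmod.RUN / "expr"
)
for row in res["summary"].itertuples():
    print(f"transition {row.transition}: {row.n_up} up, {row.n_down} down DEGs")
print(f"{res['n_deg']} distinct DEGs clustered; tables under {cfgmod.RUN / 'expr'}")
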