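"""Integrative analysis: expression stratified by promoter/enhancer marking,
lead/lag concordance of promoter marking changes with expression changes
around the focal 2->4 transition, pairwise mark-change correlations over the
DEGs, and DEG/marking overlap counts."""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfgmod = import_module("00_config")

from epidyn import pipeline

res = pipeline.run_integrate(
    cfgmod.RUN / "expr", cfgmod.RUN / "peaks", cfgmod.RUN / "annot",
    cfgmod.RUN / "integrate",
    marks=list(cfgmod.CONFIG.marks),
    focal_mark=cfgmod.CONFIG.focal_mark,
    focal_transition=(2, 4),
)
conc = res["concordance"]
sign = conc[(conc["mode"] == "sign") & (conc["mark"] == cfgmod.CONFIG.focal_mark)]
for row in sign.itertuples():
    print(
        f"{row.mark} {row.transition} {row.offset}: concordant fraction "
        f"{row.fraction_concordant:.3f} (universe {row.universe})"
    )
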