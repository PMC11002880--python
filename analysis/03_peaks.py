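"""Peak analysis per mark: master (union) peak list, fragment counts,
differential marking between consecutive timepoints, width statistics and
cross-timepoint detection overlap."""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfgmod = import_module("00_config")

from epidyn import pipeline

data = cfgmod.RUN / "data"
for mark in cfgmod.CONFIG.marks:
    res = pipeline.run_peaks(
        data / "peaks" / mark, data / "fragments" / mark, mark,
        cfgmod.RUN / "peaks" / mark,
    )
    n_sig = {f"{a}to{b}": int((df["status"] != "ns").sum())
             for (a, b), df in res["diffs"].items()}
    print(f"{mark}: {len(res['master'])} master peaks; differential regions {n_sig}")
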