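"""Generate the synthetic study: genome, cCREs, expression counts, peaks.

Writes results/run/data with gene models (BED6), the cCRE reference,
per-mark per-sample SEACR-style peak files and fragment BEDs, the RNA-seq
count matrix, and the truth tables recording every planted effect.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from importlib import import_module

cfgmod = import_module("00_config")

from epidyn import pipeline

data = cfgmod.RUN / "data"
pipeline.run_simulate(cfgmod.CONFIG, data)
n_frag_files = len(list((data / "fragments").rglob("*.bed")))
print(f"simulated {cfgmod.CONFIG.n_genes} genes on {cfgmod.CONFIG.n_chroms} chromosomes")
print(f"marks: {', '.join(cfgmod.CONFIG.marks)} ({n_frag_files} fragment files)")
print(f"truth tables under {data / 'truth'}")
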