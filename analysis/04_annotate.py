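"""cCRE-prioritised annotation of each mark's master peaks.

Assigns every peak its genomic feature, signed TSS distance, cCRE class
(PLS > dELS > pELS > other), promoter gene pairs, and for dELS peaks the
closest non-overlapping gene; also extracts the genes linked to the
strongest dELS peaks."""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfgmod = import_module("00_config")

from epidyn import pipeline

data = cfgmod.RUN / "data"
for mark in cfgmod.CONFIG.marks:
    res = pipeline.run_annotate(
        cfgmod.RUN / "peaks" / mark / "master_peaks.tsv",
        data / "genes.bed", data / "ccres.bed",
        cfgmod.RUN / "annot" / mark,
        levels_path=cfgmod.RUN / "peaks" / mark / "logcpm.tsv",
    )
    adf = res["annotation"]
    frac = (adf["ccre_class"].value_counts(normalize=True) * 100).round(1)
    print(f"{mark}: cCRE fractions (%) {frac.to_dict()}")
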