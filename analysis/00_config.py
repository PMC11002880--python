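"""Shared configuration for the numbered analysis scripts.

The run emulates the study design: 4 timepoints (1/2/4/7 days post injury),
2 replicates, RNA-seq counts plus CUT&Tag peak/fragment sets for four histone
marks, with the lactylation mark (H3K18la) carrying the planted lead/lag
coupling to expression. Everything lands under results/run.
"""

from pathlib import Path

from epidyn.synthetic import SimulationConfig

SEED = 1
RUN = Path(__file__).resolve().parent.parent / "results" / "run"
CONFIG = SimulationConfig(seed=SEED)
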