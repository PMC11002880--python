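"""Render the plain-text summary of the whole run to results/run/report.txt."""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfgmod = import_module("00_config")

from epidyn import pipeline

print(pipeline.run_report(cfgmod.RUN, cfgmod.RUN / "report.txt"))
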