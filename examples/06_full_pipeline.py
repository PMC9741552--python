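"""End-to-end simulated study: simulate -> detect -> align -> structure ->
binding -> tissues.

Runs the whole pipeline into an output directory and prints the summary.
The same run is available from the command line as:

    uhpscan run --seed 1 --out out/

Run:  python examples/06_full_pipeline.py
"""

import json
import tempfile
from pathlib import Path

from uhpscan import SimulationConfig, run_all

cfg = SimulationConfig(seed=1, n_genes=40, frac_with_event=0.5,
                       n_decoys_per_class=3)

with tempfile.TemporaryDirectory() as tmp:
    summary = run_all(cfg, tmp)
    written = sorted(p.name for p in Path(tmp).iterdir() if p.is_file())

print("files written:", ", ".join(written), "\n")
print(json.dumps(summary, indent=2, sort_keys=True))
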