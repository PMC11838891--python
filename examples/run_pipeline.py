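"""Run the full pipeline from a YAML experiment config.

Writes a config file, executes simulate -> fixed points -> TVART ->
clustering, and prints the results bundle.  All artifacts (trajectory,
attractors, temporal modes, cluster assignment, MANIFEST.json) land in
the run directory and are reproducible from the master seed alone.
"""

import json
from pathlib import Path

from tvartlab.pipeline import load_config, run_experiment

cfg_path = Path("runs/demo.yaml")
cfg_path.parent.mkdir(parents=True, exist_ok=True)
cfg_path.write_text(
    """\
preset: two_attractor
simulation:
  duration: 60.0
tvart:
  delay_steps: 31
output_dir: demo_run
master_seed: 1
"""
)

config = load_config(cfg_path)
results = run_experiment(config)
print(json.dumps(results, indent=2))
print(f"\nartifacts written to {config.output_dir}")
print("accuracy_percent scores the temporal-mode clustering against the "
      "nearest-attractor window labels; rerunning with the same master "
      "seed reproduces every file byte for byte.")
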