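"""Run the end-to-end experiment (simulate -> degrade -> segment ->
featurize -> classify -> evaluate) and inspect the report bundle.

Writes feature tables, per-model predictions, the metric grid (nine model
rows per channel), channel-agreement summaries and significance tests to
an output directory, plus a manifest with every derived seed.
"""

import json
from pathlib import Path

import pandas as pd

from gazeload.classifiers import CVScheme
from gazeload.pipeline import ExperimentConfig, run_experiment
from gazeload.synthetic import GazeSimSpec

out = Path("scratch/experiment")
config = ExperimentConfig(
    sim=GazeSimSpec(n_subjects=4, seed=3),
    cv=CVScheme(k=3, seed=3),
    deep_epochs=8,
    master_seed=3,
)
summary = run_experiment(config, out)
print(json.dumps({k: v for k, v in summary.items() if not isinstance(v, dict)}, indent=2))

grid = pd.read_csv(out / "metric_grid.csv")
print("\nmetric grid (accuracy per model and channel):")
print(grid.pivot(index="model", columns="channel", values="accuracy"))
print("\nmean final cumulative percentage between channels: "
      f"{summary['mean_final_cump']:.1f}%")
print("Re-running with the same config reproduces the classical outputs "
      "byte for byte (see manifest.json for the derived stage seeds).")
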