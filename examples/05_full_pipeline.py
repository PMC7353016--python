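"""The whole analysis in one call.

Runs every stage — exclusions, summaries, EA aggregation, outlier screen,
three-estimator variography, WLS fits, cross-validated model selection,
grid kriging and probability surfaces — and writes reproducible artifacts
with a checksum manifest.
"""

import json
from pathlib import Path

from selmap import pipeline, simulate

out = Path("pipeline_output")
config = pipeline.PipelineConfig(
    out_dir=out,
    simulation=simulate.SimulationConfig(seed=11),
    grid_spacing_km=50.0,
    cv_n_sim=1000,
)
manifest = pipeline.run(config)

print("artifacts written to", out)
for name, meta in manifest["artifacts"].items():
    print(f"  {name:<32} sha256 {meta['sha256'][:12]}…")

cv = json.loads((out / "cv_summary.json").read_text())
print(f"\nselected model cross-validation: median SSPE {cv['median_sspe']:.3f} "
      f"in ({cv['interval'][0]:.3f}, {cv['interval'][1]:.3f}) -> valid={cv['valid']}")
print("Rerunning with the same seed and config reproduces every checksum.\n"
      "If no candidate model passes cross-validation the pipeline aborts\n"
      "explicitly at the model_selection stage rather than mapping with an\n"
      "invalid variogram.")
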