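"""Deficiency-probability surface with calibrated likelihood phrases.

Kriges EA-mean serum Se of women of reproductive age onto a national
grid and converts predictions + kriging variances into the probability of
falling below the GPx3 threshold (84.9 µg/L), phrased on the IPCC scale.
"""

import pandas as pd

from selmap import cohort, kriging, risk, simulate, variogram

cfg = simulate.SimulationConfig(seed=7)
ea = cohort.aggregate_by_ea(simulate.simulate_survey(cfg), group="WRA")
model = variogram.fit_wls(
    variogram.estimate(variogram.build_cloud(ea), estimator="matheron")).model

grid = risk.make_grid(cfg.bbox, spacing_km=50.0)
preds = kriging.ok_predict(model, ea, grid["lat"].to_numpy(),
                           grid["lon"].to_numpy())
print(f"kriged {len(preds)} grid nodes; predictions "
      f"{preds['prediction'].min():.1f}-{preds['prediction'].max():.1f} µg/L, "
      f"kriging variance {preds['kriging_variance'].min():.1f}-"
      f"{preds['kriging_variance'].max():.1f} (µg/L)^2")

surface = risk.build_surface(preds, cohort.GPX3_THRESHOLD)
counts = surface["phrase"].value_counts()
share = (100 * counts / len(surface)).round(1)
print(f"\nP(serum Se < {cohort.GPX3_THRESHOLD.value} µg/L) by node, "
      "as calibrated phrases:")
print(pd.DataFrame({"nodes": counts, "percent": share}).to_string())
print("\n'likely' through 'virtually certain' nodes mark areas where the "
      "population is probably selenium deficient by the GPx3 criterion.")
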