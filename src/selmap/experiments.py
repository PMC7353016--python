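"""Repeatable simulation experiments used to validate the pipeline.

Both experiments treat the cross-validated exponential model of the
national serum Se field as the generating truth and check that the
package's estimators recover it:

* :func:`parameter_recovery` — simulate Gaussian random fields at
  uniformly placed enumeration-area locations, re-estimate the variogram
  (Matheron + weighted least squares) for each, and summarise the fitted
  parameters across replicates.
* :func:`sspe_calibration` — leave-one-out cross-validation under the true
  model should yield a median standardized squared prediction error inside
  its Monte-Carlo 95% interval (which brackets the chi-square(1) median
  0.455) in nearly all replicate experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import kriging, variogram
from .simulate import DEFAULT_FIELD_MODEL, ETHIOPIA_BBOX, SimulationConfig, \
    simulate_ea_locations, simulate_grf

__all__ = ["parameter_recovery", "sspe_calibration"]


def parameter_recovery(model=DEFAULT_FIELD_MODEL, n_sims: int = 300,
                       n_eas: int = 345, bbox=ETHIOPIA_BBOX,
                       mean: float = 100.0, seed: int = 0) -> pd.DataFrame:
    """Fit the exponential model to ``n_sims`` independent field draws.

    Each replicate places ``n_eas`` locations uniformly in ``bbox``, draws
    one Gaussian field from ``model``, estimates the Matheron variogram
    with the package defaults and refits by WLS. Returns one row per
    replicate with columns c0, c1, a; the column means are the recovery
    summary."""
    if n_sims < 1:
        raise ValueError("need at least one simulation")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_sims):
        locs = simulate_ea_locations(SimulationConfig(
            seed=int(rng.integers(2 ** 31)), n_eas=n_eas, bbox=bbox))
        z = simulate_grf(model, locs["lat"], locs["lon"], mean, rng)
        cloud = variogram.build_cloud(locs.assign(mean_se=z))
        emp = variogram.estimate(cloud, estimator="matheron")
        fit = variogram.fit_wls(emp)
        rows.append({"c0": fit.model.c0, "c1": fit.model.c1, "a": fit.model.a})
    return pd.DataFrame(rows)


def sspe_calibration(model=DEFAULT_FIELD_MODEL, n_replicates: int = 20,
                     n_eas: int = 100, bbox=ETHIOPIA_BBOX, mean: float = 100.0,
                     n_sim: int = 500, seed: int = 0) -> pd.DataFrame:
    """LOO cross-validation of the true model on fields simulated from it.

    Returns one row per replicate with the median SSPE, its Monte-Carlo
    95% interval at that replicate's layout, and whether the median fell
    inside. Under a correct model ~95% of replicates should."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        locs = simulate_ea_locations(SimulationConfig(
            seed=int(rng.integers(2 ** 31)), n_eas=n_eas, bbox=bbox))
        lat = locs["lat"].to_numpy()
        lon = locs["lon"].to_numpy()
        z = simulate_grf(model, lat, lon, mean, rng)
        lo, hi = kriging.median_sspe_interval(
            model, lat, lon, n_sim=n_sim, seed=int(rng.integers(2 ** 31)))
        report = kriging.loo_cross_validate(model, (lat, lon, z),
                                            interval=(lo, hi))
        rows.append({"median_sspe": report.median_sspe, "lo": lo, "hi": hi,
                     "valid": report.valid})
    return pd.DataFrame(rows)
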