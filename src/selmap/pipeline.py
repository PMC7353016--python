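"""End-to-end orchestration: survey -> summaries -> EA aggregation ->
outlier screen -> variography -> model selection -> kriging -> risk maps.

`run` executes the whole analysis from a :class:`PipelineConfig` and writes
every artifact (CSV/JSON) plus a manifest with SHA-256 checksums, so a
rerun with the same seed and config is byte-identical. Each stage is also
callable on its own through the library API; the pipeline only sequences
them.

The outlier handling mirrors the study's protocol: an enumeration-area
mean flagged as a probable outlier by the Tukey outer fences is removed
from variogram estimation, but reinstated as data for kriging prediction
(and, optionally, as a cross-validation target).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, kriging, risk, simulate, variogram

__all__ = ["PipelineConfig", "run"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for one pipeline run. Either ``input_csv`` (a survey file)
    or ``simulation`` (a :class:`~selmap.simulate.SimulationConfig`) must
    be given."""
    out_dir: str | Path
    input_csv: str | Path | None = None
    simulation: simulate.SimulationConfig | None = None
    group: str = "WRA"
    thresholds: tuple = cohort.DEFAULT_THRESHOLDS
    n_bins: int = 25
    min_pairs: int = 30
    n_directions: int = 4
    weight_scheme: str = "npairs"
    n_starts: int = 3
    cv_n_sim: int = 1000
    cv_seed: int = 0
    grid_spacing_km: float = 10.0
    cv_include_outlier: bool = False
    weighted_summaries: bool = True

    def __post_init__(self):
        if (self.input_csv is None) == (self.simulation is None):
            raise ValueError("give exactly one of input_csv or simulation")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(self.input_csv)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute every stage and return the artifact manifest.

    Any stage failure aborts with the stage name attached; artifacts
    written before the failure are listed in the partial manifest saved to
    the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "init"

    def write_df(name, df):
        path = out / name
        df.to_csv(path, index=False)
        artifacts[name] = path

    def write_text(name, text):
        path = out / name
        path.write_text(text)
        artifacts[name] = path

    try:
        stage = "load"
        if config.input_csv is not None:
            records = cohort.read_survey_csv(config.input_csv)
        else:
            records = simulate.simulate_survey(config.simulation)
            write_df("survey.csv", records)
        log.info("loaded %d survey records", len(records))

        stage = "exclusions"
        # individual-level screen: Tukey outer fences on serum Se
        has_se = records.dropna(subset=["serum_se_ugL"])
        _, flags = cohort.tukey_outliers(has_se["serum_se_ugL"].to_numpy())
        outlier_ids = set(has_se.loc[flags, "person_id"])
        retained, excl = cohort.apply_exclusions(records, outlier_ids)
        write_text("exclusion_log.json", excl.to_json())
        log.info("retained %d of %d records", excl.n_retained, excl.n_input)

        stage = "summaries"
        tables = [cohort.summarize(retained, strat, config.thresholds,
                                   weighted=config.weighted_summaries)
                  for strat in ("national", "region", "group")]
        write_df("summary.csv", pd.concat(tables, ignore_index=True))

        stage = "ea_aggregation"
        ea = cohort.aggregate_by_ea(retained, group=config.group)
        write_df("ea_means.csv", ea)

        stage = "ea_outlier_screen"
        fences, ea_flags = cohort.tukey_outliers(ea["mean_se"].to_numpy())
        ea_vario = ea[~ea_flags]       # variogram never sees the flagged EA
        log.info("EA outlier screen: %d probable outlier(s); fences %s",
                 int(ea_flags.sum()), fences.outer)

        stage = "variograms"
        cloud = variogram.build_cloud(ea_vario)
        edges = variogram.default_bin_edges(cloud, config.n_bins)
        fits = {}
        for est in variogram.ESTIMATORS:
            emp = variogram.estimate(cloud, edges, est, config.min_pairs)
            write_df(f"variogram_{est}.csv", emp.bins)
            fits[est] = variogram.fit_wls(emp, weight_scheme=config.weight_scheme,
                                          n_starts=config.n_starts).model
        directional = variogram.directional_variograms(
            cloud, config.n_directions, edges, "matheron", config.min_pairs)
        write_df("variogram_directional.csv",
                 pd.concat([d.bins.assign(bearing_class=d.bearing_class)
                            for d in directional], ignore_index=True))

        stage = "model_selection"
        cv_data = ea if config.cv_include_outlier else ea_vario
        selection = kriging.select_model(fits, cv_data, n_sim=config.cv_n_sim,
                                         seed=config.cv_seed)
        if selection.status != "selected":
            raise RuntimeError(
                "no variogram model passed cross-validation: "
                + json.dumps(selection.audit, default=str))
        model = selection.model
        write_text("model.json", model.to_json(
            estimator=selection.chosen, audit=selection.audit))
        report = kriging.loo_cross_validate(model, cv_data,
                                            interval=selection.audit[-1]["interval"])
        write_df("cv_report.csv", report.table)
        write_text("cv_summary.json", json.dumps({
            "median_sspe": report.median_sspe,
            "interval": report.interval,
            "valid": report.valid,
            "expected": kriging.SSPE_MEDIAN_EXPECTED,
        }, indent=2))

        stage = "kriging"
        bbox = (config.simulation.bbox if config.simulation is not None
                else (ea["lon"].min(), ea["lat"].min(),
                      ea["lon"].max(), ea["lat"].max()))
        grid = risk.make_grid(bbox, config.grid_spacing_km)
        # flagged EA mean is reinstated for prediction
        preds = kriging.ok_predict(model, ea, grid["lat"].to_numpy(),
                                   grid["lon"].to_numpy())
        write_df("predictions.csv", preds)

        stage = "risk_mapping"
        for t in config.thresholds:
            surface = risk.build_surface(preds, t)
            write_df(f"probability_{t.label.lower()}.csv", surface)

        stage = "manifest"
        manifest = {
            "config": json.loads(json.dumps(asdict(config), default=str)),
            "artifacts": {name: {"path": str(p), "sha256": _sha256(p)}
                          for name, p in sorted(artifacts.items())},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        partial = {name: str(p) for name, p in artifacts.items()}
        (out / "manifest_partial.json").write_text(json.dumps(
            {"failed_stage": stage, "error": str(exc), "artifacts": partial},
            indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
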