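"""Synthetic survey generator.

The real serum dataset is restricted, so every pipeline stage is exercised
on simulated surveys built to the same anatomy: enumeration-area (EA) mean
serum Se follows a Gaussian random field with exponential covariance on
great-circle distances (nugget realised as iid noise — the
measurement-error reading of spatially uncorrelated variance); individuals
within an EA scatter around the EA mean; demographic composition, survey
weights and the missing-GPS / missing-demographics / outlier exclusion
structure are reproduced at configurable rates or exact counts.

Defaults state the study's world: 346 EAs in a lon 33-48 E, lat 3-15 N
bounding box, field parameters c0 = 2.51, c1 = 26.23 (µg/L)^2 and
a = 132.8 km, and the published group composition (584 YC, 1034 SAC,
419 men, 1339 WRA drawn for analysis; 3376 records in all).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .cohort import SURVEY_COLUMNS
from .geodesy import great_circle_distance
from .variogram import ExponentialVariogramModel

__all__ = [
    "ETHIOPIA_BBOX",
    "DEFAULT_FIELD_MODEL",
    "SimulationConfig",
    "simulate_ea_locations",
    "simulate_grf",
    "simulate_survey",
    "make_fixture_enms_counts",
]

#: Coarse national bounding box (lon_min, lat_min, lon_max, lat_max).
ETHIOPIA_BBOX = (33.0, 3.0, 48.0, 15.0)

#: Generating truth for the EA-mean field: the cross-validated exponential
#: model (nugget, partial sill, distance parameter).
DEFAULT_FIELD_MODEL = ExponentialVariogramModel(c0=2.51, c1=26.23, a=132.8)

# Serum samples analysed per demographic group (before exclusions).
_DEFAULT_GROUP_TOTALS = {"YC": 584, "SAC": 1034, "MEN": 419, "WRA": 1339}

_REGIONS = ("Addis Ababa", "Afar", "Amhara", "Benishangul-Gumuz", "Dire Dawa",
            "Gambela", "Harari", "Oromia", "SNNP", "Somali", "Tigray")


@dataclass
class SimulationConfig:
    """Stated world of a synthetic survey; every field has a documented
    default and the seed is mandatory."""
    seed: int
    n_eas: int = 346
    bbox: tuple = ETHIOPIA_BBOX
    c0: float = DEFAULT_FIELD_MODEL.c0
    c1: float = DEFAULT_FIELD_MODEL.c1
    a_km: float = DEFAULT_FIELD_MODEL.a
    mean_se: float = 100.0            # µg/L, field mean of EA-level serum Se
    # Individual scatter about the EA mean. Kept small so the sampling
    # noise an EA mean inherits (sd^2 / ~4 individuals per group-EA) stays
    # on the order of the EA-level nugget 2.51 (µg/L)^2 — larger values
    # would bury the stated EA-level covariance under aggregation noise.
    within_ea_sd: float = 3.0         # µg/L
    group_totals: dict = field(default_factory=lambda: dict(_DEFAULT_GROUP_TOTALS))
    gps_missing_rate: float = 0.0
    demographic_missing_rate: float = 0.0
    n_outliers: int = 0
    outlier_value: float = 1000.0     # µg/L, injected extreme serum value
    urban_share: float = 0.257

    def __post_init__(self):
        if self.c0 < 0 or self.c1 < 0 or self.a_km <= 0 or self.within_ea_sd < 0:
            raise ValueError("variance parameters must be non-negative (a > 0)")
        for r in (self.gps_missing_rate, self.demographic_missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("missingness rates must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def model(self) -> ExponentialVariogramModel:
        return ExponentialVariogramModel(self.c0, self.c1, self.a_km)


def simulate_ea_locations(config: SimulationConfig) -> pd.DataFrame:
    """Uniform EA locations inside the bounding box, deterministic per seed."""
    if config.n_eas < 2:
        raise ValueError("need at least 2 enumeration areas")
    lon_min, lat_min, lon_max, lat_max = config.bbox
    if lon_min >= lon_max or lat_min >= lat_max:
        raise ValueError("degenerate bounding box")
    rng = np.random.default_rng(config.seed)
    return pd.DataFrame({
        "ea_id": [f"EA{k:04d}" for k in range(config.n_eas)],
        "lat": rng.uniform(lat_min, lat_max, config.n_eas),
        "lon": rng.uniform(lon_min, lon_max, config.n_eas),
    })


def simulate_grf(model: ExponentialVariogramModel, lat, lon, mean: float,
                 rng: np.random.Generator, jitter: float = 1e-8) -> np.ndarray:
    """One draw of the Gaussian field with covariance c1*exp(-h/a) plus an
    independent nugget c0, by dense Cholesky factorization.

    Suited to a few thousand locations at most. A small diagonal jitter
    (1e-8 of the sill) keeps the factorization stable; failure even then
    raises.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    D = great_circle_distance(lat[:, None], lon[:, None],
                              lat[None, :], lon[None, :])
    C = model.covariance(D) + (model.c0 + jitter * max(model.sill, 1.0)) * np.eye(lat.size)
    try:
        L = cholesky(C, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise RuntimeError("covariance matrix not positive definite") from exc
    return mean + L @ rng.standard_normal(lat.size)


def _draw_positive(rng, loc, sd, size):
    """Gaussian draws resampled until above 1 µg/L (serum Se cannot be
    non-positive; negligible truncation at the default mean/sill)."""
    out = rng.normal(loc, sd, size)
    for _ in range(100):
        bad = out < 1.0
        if not bad.any():
            break
        out[bad] = rng.normal(loc if np.isscalar(loc) else loc[bad], sd, bad.sum())
    return np.maximum(out, 1.0)


def simulate_survey(config: SimulationConfig,
                    gps_missing_counts: dict | None = None,
                    demographic_missing_counts: dict | None = None
                    ) -> pd.DataFrame:
    """Full synthetic survey in the standard record layout.

    EA means come from one field draw; individuals are allocated to EAs
    round-robin within each demographic group (so configured group totals
    are met exactly), with serum = EA mean + within-EA noise, truncated
    positive. Missingness is then applied: per-group exact counts when
    ``*_missing_counts`` are given, otherwise Bernoulli at the configured
    rates. ``n_outliers`` records from the WRA group get an extreme serum
    value so the Tukey outer-fence screen has something to find.
    """
    rng = np.random.default_rng(config.seed)
    eas = simulate_ea_locations(config)
    ea_mean = _draw_positive(
        rng,
        simulate_grf(config.model, eas["lat"], eas["lon"], config.mean_se, rng),
        0.0, len(eas))

    frames = []
    counter = 0
    for g, total in config.group_totals.items():
        if total < 0:
            raise ValueError("group totals must be non-negative")
        ea_idx = np.arange(total) % len(eas)           # round-robin allocation
        serum = _draw_positive(rng, ea_mean[ea_idx], config.within_ea_sd, total)
        if g == "MEN":
            sex = np.full(total, "M")
        elif g == "WRA":
            sex = np.full(total, "F")
        else:
            sex = rng.choice(["M", "F"], size=total)
        frames.append(pd.DataFrame({
            "person_id": [f"P{counter + k:05d}" for k in range(total)],
            "ea_id": eas["ea_id"].to_numpy()[ea_idx],
            "region": rng.choice(_REGIONS, size=total),
            "group": g,
            "sex": sex,
            "residence": rng.choice(["urban", "rural"], size=total,
                                    p=[config.urban_share, 1 - config.urban_share]),
            "weight": rng.uniform(0.5, 1.5, total),
            "lat": eas["lat"].to_numpy()[ea_idx],
            "lon": eas["lon"].to_numpy()[ea_idx],
            "serum_se_ugL": serum,
        }))
        counter += total
    df = pd.concat(frames, ignore_index=True)[SURVEY_COLUMNS]

    def knockout(columns, counts, rate):
        hit = np.zeros(len(df), dtype=bool)
        if counts is not None:
            for g, k in counts.items():
                pool = np.flatnonzero((df["group"] == g).to_numpy() & ~_consumed)
                if k > pool.size:
                    raise ValueError(f"cannot remove {k} records from group {g}")
                hit[rng.choice(pool, size=k, replace=False)] = True
        elif rate > 0:
            hit = rng.random(len(df)) < rate
            hit &= ~_consumed
        df.loc[hit, columns] = np.nan
        return hit

    _consumed = np.zeros(len(df), dtype=bool)
    _consumed |= knockout(["lat", "lon"], gps_missing_counts, config.gps_missing_rate)
    _consumed |= knockout(["group", "sex"], demographic_missing_counts,
                          config.demographic_missing_rate)

    if config.n_outliers:
        pool = np.flatnonzero((df["group"] == "WRA").to_numpy() & ~_consumed)
        chosen = rng.choice(pool, size=config.n_outliers, replace=False)
        df.loc[chosen, "serum_se_ugL"] = config.outlier_value
    return df


def make_fixture_enms_counts(seed: int = 20150) -> pd.DataFrame:
    """Deterministic 3376-record fixture reproducing the published survey
    anatomy exactly.

    Exclusion structure: GPS coordinates missing for 101 records (5 men,
    63 young children, 24 school-age children, 9 women), a demographic
    item missing for 5 (3 school-age children, 2 women), and one extreme
    serum value among the women, leaving 3269 analysable records. Among
    those retained the published composition is reproduced exactly:
    841 urban / 2428 rural, 284 male young children and 451 male
    school-age children.
    """
    config = SimulationConfig(seed=seed, n_outliers=1)
    df = simulate_survey(
        config,
        gps_missing_counts={"MEN": 5, "YC": 63, "SAC": 24, "WRA": 9},
        demographic_missing_counts={"SAC": 3, "WRA": 2},
    )
    excluded = (df["lat"].isna() | df["group"].isna()
                | (df["serum_se_ugL"] == config.outlier_value))
    retained = np.flatnonzero(~excluded.to_numpy())
    # residence: first 841 retained urban, the remaining 2428 rural
    df.loc[df.index[retained], "residence"] = np.where(
        np.arange(retained.size) < 841, "urban", "rural")
    # sex splits among retained children per the published counts
    for g, n_male in (("YC", 284), ("SAC", 451)):
        rows = retained[(df["group"].to_numpy()[retained] == g)]
        df.loc[df.index[rows], "sex"] = np.where(
            np.arange(rows.size) < n_male, "M", "F")
    return df
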