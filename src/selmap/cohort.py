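"""Survey-record handling: loading, exclusions, weighted summaries,
deficiency thresholds and enumeration-area aggregation.

Records travel as a pandas DataFrame with the columns

    person_id, ea_id, region, group, sex, residence, weight, lat, lon,
    serum_se_ugL

where ``group`` is one of YC (young children), SAC (school-age children),
MEN, WRA (women of reproductive age); missing entries are NaN/None. Serum
selenium is in µg/L. The enumeration area (EA) is the spatial unit: serum
values are averaged per EA, with mean coordinates, before any variography.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "SURVEY_COLUMNS",
    "SE_MOLAR_MASS",
    "DeficiencyThreshold",
    "GPX3_THRESHOLD",
    "IDI_THRESHOLD",
    "CONVENTIONAL_THRESHOLD",
    "ExclusionLog",
    "TukeyFences",
    "read_survey_csv",
    "apply_exclusions",
    "weighted_quantiles",
    "prevalence_below",
    "summarize",
    "threshold_from_molar_range",
    "tukey_outliers",
    "aggregate_by_ea",
]

GROUPS = ("YC", "SAC", "MEN", "WRA")

SURVEY_COLUMNS = [
    "person_id", "ea_id", "region", "group", "sex", "residence",
    "weight", "lat", "lon", "serum_se_ugL",
]

#: Molar mass of selenium, g/mol.
SE_MOLAR_MASS = 78.97

_DEMOGRAPHIC_COLS = ["region", "group", "sex", "residence"]


@dataclass(frozen=True)
class DeficiencyThreshold:
    """A serum Se deficiency cut-off in µg/L; status is deficient when the
    concentration is strictly below ``value``."""
    label: str
    value: float

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("threshold must be non-negative")


def threshold_from_molar_range(lo: float, hi: float,
                               molar_mass: float = SE_MOLAR_MASS) -> float:
    """Serum threshold in µg/L from a molar range: midpoint of
    [lo, hi] µmol/L converted with the Se molar mass, rounded to 0.1.

    The glutathione-peroxidase-3 (GPx3) threshold is derived this way from
    the 1.00-1.15 µmol/L range for optimal enzyme activity, giving
    84.9 µg/L.
    """
    if lo < 0 or hi < 0:
        raise ValueError("molar concentrations must be non-negative")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    return round(0.5 * (lo + hi) * molar_mass, 1)


GPX3_THRESHOLD = DeficiencyThreshold("GPX3", threshold_from_molar_range(1.00, 1.15))
IDI_THRESHOLD = DeficiencyThreshold("IDI", 64.8)
CONVENTIONAL_THRESHOLD = DeficiencyThreshold("CONVENTIONAL", 70.0)

DEFAULT_THRESHOLDS = (CONVENTIONAL_THRESHOLD, GPX3_THRESHOLD, IDI_THRESHOLD)


@dataclass
class ExclusionLog:
    """Audit of record exclusions, applied in fixed precedence
    missing GPS -> missing demographic -> outlier (each record counted
    once, under the first reason that applies)."""
    n_input: int
    n_missing_gps: int
    n_missing_demographic: int
    n_outlier: int
    n_retained: int
    by_group: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = (self.n_input - self.n_missing_gps
                    - self.n_missing_demographic - self.n_outlier)
        if self.n_retained != expected:
            raise ValueError("exclusion log does not reconcile")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def read_survey_csv(path) -> pd.DataFrame:
    """Read the survey CSV dialect (UTF-8, decimal point, empty string =
    missing) and validate column set and basic invariants."""
    df = pd.read_csv(path, dtype={"person_id": str, "ea_id": str},
                     keep_default_na=True, na_values=[""])
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survey CSV missing columns: {sorted(missing)}")
    df = df[SURVEY_COLUMNS].copy()
    _validate_survey(df)
    return df


def _validate_survey(df: pd.DataFrame) -> None:
    lat, lon = df["lat"], df["lon"]
    if ((lat.dropna().abs() > 90).any() or (lon.dropna().abs() > 180).any()):
        raise ValueError("coordinates outside valid WGS84 range")
    if (df["serum_se_ugL"].dropna() <= 0).any():
        raise ValueError("serum Se must be positive when present")
    if (df["weight"].dropna() < 0).any():
        raise ValueError("survey weights must be non-negative")
    bad = set(df["group"].dropna()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown demographic group labels: {sorted(bad)}")


def apply_exclusions(records: pd.DataFrame,
                     outlier_ids: Iterable = ()) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop records with missing GPS, then missing demographics, then the
    flagged outliers; return retained records and a reconciled log.

    ``outlier_ids`` are person_id values flagged upstream (e.g. by the
    Tukey outer-fence rule); an id absent from the input is an error.
    """
    if len(records) == 0:
        raise ValueError("no records to filter")
    outlier_ids = set(outlier_ids)
    unknown = outlier_ids - set(records["person_id"])
    if unknown:
        raise KeyError(f"outlier ids not present in records: {sorted(unknown)}")

    miss_gps = records["lat"].isna() | records["lon"].isna()
    miss_demo = records[_DEMOGRAPHIC_COLS].isna().any(axis=1) & ~miss_gps
    is_outl = (records["person_id"].isin(outlier_ids)
               & ~miss_gps & ~miss_demo)
    retained = records[~(miss_gps | miss_demo | is_outl)].copy()

    def per_group(mask):
        sub = records.loc[mask, "group"]
        return {g: int((sub == g).sum()) for g in GROUPS}

    log = ExclusionLog(
        n_input=len(records),
        n_missing_gps=int(miss_gps.sum()),
        n_missing_demographic=int(miss_demo.sum()),
        n_outlier=int(is_outl.sum()),
        n_retained=len(retained),
        by_group={
            "missing_gps": per_group(miss_gps),
            "missing_demographic": per_group(miss_demo),
            "outlier": per_group(is_outl),
        },
    )
    return retained, log


def weighted_quantiles(values, weights, probs) -> np.ndarray:
    """Weighted quantiles by inverse cumulative-weight CDF.

    Duplicate values are pooled; when a probability lands exactly on a
    cumulative-weight boundary between two distinct values the result is
    their midpoint (linear interpolation at the jump), so equal weights
    reproduce the ordinary sample median.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    p = np.atleast_1d(np.asarray(probs, dtype=float))
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if v.size == 0:
        raise ValueError("empty input")
    if (w < 0).any():
        raise ValueError("negative weights")
    if not (w > 0).any():
        raise ValueError("all weights are zero")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")

    keep = w > 0
    v, w = v[keep], w[keep]
    order = np.argsort(v)
    v, w = v[order], w[order]
    # pool duplicate values so boundaries are boundaries of the distribution
    vu, idx = np.unique(v, return_inverse=True)
    wu = np.bincount(idx, weights=w)
    cw = np.cumsum(wu)
    total = cw[-1]

    out = np.empty(p.shape)
    for m, prob in enumerate(p):
        target = prob * total
        k = int(np.searchsorted(cw, target, side="left"))
        if k >= vu.size:
            out[m] = vu[-1]
        elif np.isclose(cw[k], target) and k + 1 < vu.size:
            out[m] = 0.5 * (vu[k] + vu[k + 1])
        else:
            out[m] = vu[k]
    return out if np.ndim(probs) else float(out[0])


def prevalence_below(values, weights, threshold) -> float:
    """Weighted percentage of values strictly below the threshold."""
    t = threshold.value if isinstance(threshold, DeficiencyThreshold) else float(threshold)
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if not (w > 0).any():
        raise ValueError("all weights are zero")
    return float(100.0 * w[v < t].sum() / w.sum())


def summarize(records: pd.DataFrame, stratifier: str = "national",
              thresholds: Sequence[DeficiencyThreshold] = DEFAULT_THRESHOLDS,
              weighted: bool = True) -> pd.DataFrame:
    """Per-stratum serum Se summaries: n, median, quartiles and prevalence
    below each threshold.

    ``stratifier`` is ``"region"``, ``"group"`` or ``"national"``. Records
    with missing serum values are dropped (with a warning). ``weighted``
    toggles survey-weighted versus unweighted quantiles and prevalence;
    weighted is the default, matching the use of survey weights for
    summary statistics.
    """
    if stratifier not in ("region", "group", "national"):
        raise ValueError("stratifier must be region, group or national")
    df = records
    n_missing_se = int(df["serum_se_ugL"].isna().sum())
    if n_missing_se:
        warnings.warn(f"dropping {n_missing_se} records with missing serum Se")
        df = df.dropna(subset=["serum_se_ugL"])
    if stratifier == "national":
        strata = [("National", df)]
    else:
        strata = list(df.groupby(stratifier, observed=True))

    rows = []
    for label, sub in strata:
        if len(sub) == 0:
            warnings.warn(f"stratum {label!r} has no records; omitted")
            continue
        v = sub["serum_se_ugL"].to_numpy()
        w = (sub["weight"].to_numpy() if weighted
             else np.ones(len(sub)))
        q1, med, q3 = weighted_quantiles(v, w, [0.25, 0.5, 0.75])
        row = {"stratum": label, "n": len(sub),
               "median": med, "q1": q1, "q3": q3}
        for t in thresholds:
            row[f"prevalence_{t.label.lower()}"] = prevalence_below(v, w, t)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TukeyFences:
    """Quartile-based outlier fences: values beyond the inner fences
    (1.5 IQR) are possible outliers, beyond the outer fences (3 IQR)
    probable outliers."""
    q1: float
    q3: float
    inner: tuple[float, float]
    outer: tuple[float, float]


def tukey_outliers(values) -> tuple[TukeyFences, np.ndarray]:
    """Tukey fences and a boolean flag per value marking probable outliers
    (beyond the outer fences). Quartiles use linear interpolation on the
    unweighted sample. Requires n >= 4."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("Tukey fences need at least 4 values")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    fences = TukeyFences(
        q1=float(q1), q3=float(q3),
        inner=(float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)),
        outer=(float(q1 - 3.0 * iqr), float(q3 + 3.0 * iqr)),
    )
    flags = (v < fences.outer[0]) | (v > fences.outer[1])
    return fences, flags


def aggregate_by_ea(records: pd.DataFrame, group: str | None = "WRA") -> pd.DataFrame:
    """Aggregate individual records to enumeration-area means.

    Returns one row per EA with mean serum Se, arithmetic-mean coordinates
    in degrees (EAs are tiny relative to the spatial range of the field,
    so planar averaging is harmless) and the contributing count n.
    Records missing coordinates or serum values are ignored; EAs left with
    no eligible record are omitted.
    """
    df = records
    if group is not None:
        df = df[df["group"] == group]
    df = df.dropna(subset=["lat", "lon", "serum_se_ugL"])
    if len(df) == 0:
        raise ValueError("no eligible records to aggregate")
    agg = (df.groupby("ea_id", observed=True)
             .agg(lat=("lat", "mean"), lon=("lon", "mean"),
                  mean_se=("serum_se_ugL", "mean"), n=("serum_se_ugL", "size"))
             .reset_index())
    agg["n"] = agg["n"].astype(int)
    return agg
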