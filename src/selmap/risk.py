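"""Deficiency-probability surfaces and calibrated likelihood phrases.

Under ordinary kriging the prediction distribution at a location is taken
as Gaussian with the OK mean and kriging variance, so the probability that
the enumeration-area mean serum Se falls below a threshold t is the
plug-in value Phi((t - zhat) / sigma). Probabilities are translated into
the calibrated verbal likelihood phrases popularised by the IPCC
("likely", "virtually certain", ...) for communication with audiences
unfamiliar with probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from shapely.geometry import Point, box
from shapely.prepared import prep

from .cohort import DeficiencyThreshold
from .geodesy import EARTH_RADIUS_KM

__all__ = [
    "LikelihoodScale",
    "IPCC_SCALE",
    "prob_below",
    "classify",
    "make_grid",
    "build_surface",
    "surface_to_geojson",
]


@dataclass(frozen=True)
class LikelihoodScale:
    """Ordered probability bins covering [0, 1] with unique labels.

    ``bounds`` are the n+1 edges of n bins; bin k covers
    [bounds[k], bounds[k+1]), the last bin closed above. A probability on
    an interior boundary therefore belongs to the upper bin.
    """
    bounds: tuple
    labels: tuple

    def __post_init__(self):
        b = np.asarray(self.bounds, dtype=float)
        if b[0] != 0.0 or b[-1] != 1.0 or (np.diff(b) <= 0).any():
            raise ValueError("bounds must increase strictly from 0 to 1")
        if len(self.labels) != b.size - 1:
            raise ValueError("need exactly one label per bin")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")


#: IPCC-style calibrated phrases, made non-overlapping (the published
#: guidance ranges overlap at their endpoints).
IPCC_SCALE = LikelihoodScale(
    bounds=(0.0, 0.01, 0.10, 0.33, 0.66, 0.90, 0.99, 1.0),
    labels=("exceptionally unlikely", "very unlikely", "unlikely",
            "about as likely as not", "likely", "very likely",
            "virtually certain"),
)


def prob_below(prediction, kriging_variance, threshold) -> np.ndarray | float:
    """Probability that the true value at a node lies below the threshold,
    Phi((t - zhat)/sigma) under the Gaussian prediction distribution.

    With zero kriging variance the distribution is degenerate: the
    probability is 1 below the threshold, 0 above, 0.5 at equality.
    """
    t = threshold.value if isinstance(threshold, DeficiencyThreshold) else float(threshold)
    zhat = np.asarray(prediction, dtype=float)
    var = np.asarray(kriging_variance, dtype=float)
    if (var < 0).any():
        raise ValueError("negative kriging variance")
    sigma = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = norm.cdf((t - zhat) / sigma)
    degenerate = sigma == 0.0
    p = np.where(degenerate, np.where(zhat < t, 1.0, np.where(zhat > t, 0.0, 0.5)), p)
    return p if p.shape else float(p)


def classify(p, scale: LikelihoodScale = IPCC_SCALE):
    """Phrase label for a probability (vectorised). Interior boundaries go
    to the upper bin; p must lie in [0, 1]."""
    parr = np.asarray(p, dtype=float)
    if ((parr < 0) | (parr > 1)).any() or not np.isfinite(parr).all():
        raise ValueError("probability outside [0, 1]")
    lower = np.asarray(scale.bounds[:-1])
    idx = np.clip(np.searchsorted(lower, parr, side="right") - 1, 0, len(scale.labels) - 1)
    labels = np.asarray(scale.labels, dtype=object)[idx]
    return labels if parr.shape else str(labels)


def make_grid(boundary, spacing_km: float) -> pd.DataFrame:
    """Regular lattice of nodes covering a boundary, as (lat, lon) rows.

    ``boundary`` is a shapely polygon or a (lon_min, lat_min, lon_max,
    lat_max) bbox tuple. Spacing in km is converted to degrees at the
    domain's central latitude (meridional degree = pi R / 180); nodes
    outside the boundary are dropped. The lattice starts at the south-west
    corner, so a spacing wider than the extent still yields that corner
    node.
    """
    if spacing_km <= 0:
        raise ValueError("spacing must be positive")
    poly = box(*boundary) if isinstance(boundary, (tuple, list)) else boundary
    lon_min, lat_min, lon_max, lat_max = poly.bounds
    deg_km = np.pi * EARTH_RADIUS_KM / 180.0  # km per degree of latitude
    dlat = spacing_km / deg_km
    central_lat = 0.5 * (lat_min + lat_max)
    dlon = dlat / max(np.cos(np.radians(central_lat)), 1e-9)
    lats = np.arange(lat_min, lat_max + 1e-12, dlat)
    lons = np.arange(lon_min, lon_max + 1e-12, dlon)
    glon, glat = np.meshgrid(lons, lats)
    glon, glat = glon.ravel(), glat.ravel()
    prepared = prep(poly.buffer(1e-9))
    inside = np.fromiter((prepared.contains(Point(x, y))
                          for x, y in zip(glon, glat)), bool, count=glon.size)
    if not inside.any():
        raise ValueError("no grid nodes fall inside the boundary")
    return pd.DataFrame({"lat": glat[inside], "lon": glon[inside]})


def build_surface(predictions: pd.DataFrame, threshold: DeficiencyThreshold,
                  scale: LikelihoodScale = IPCC_SCALE) -> pd.DataFrame:
    """Per-node probability of sub-threshold status plus calibrated phrase.

    ``predictions`` is the output of ``ok_predict`` (lat, lon, prediction,
    kriging_variance). The result carries the threshold in its attrs for
    provenance.
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to convert")
    if threshold.value <= 0:
        raise ValueError("threshold must be positive")
    p = prob_below(predictions["prediction"].to_numpy(),
                   predictions["kriging_variance"].to_numpy(), threshold)
    out = pd.DataFrame({
        "lat": predictions["lat"].to_numpy(),
        "lon": predictions["lon"].to_numpy(),
        "probability": np.atleast_1d(p),
    })
    out["phrase"] = classify(out["probability"].to_numpy(), scale)
    out.attrs["threshold_label"] = threshold.label
    out.attrs["threshold_ugL"] = threshold.value
    out.attrs["phrases"] = list(scale.labels)
    return out


def surface_to_geojson(surface: pd.DataFrame) -> str:
    """Serialize a probability surface as a GeoJSON FeatureCollection of
    points (lon, lat order per the GeoJSON convention)."""
    features = [
        {"type": "Feature",
         "geometry": {"type": "Point", "coordinates": [float(r.lon), float(r.lat)]},
         "properties": {"probability": float(r.probability), "phrase": str(r.phrase)}}
        for r in surface.itertuples()
    ]
    return json.dumps({
        "type": "FeatureCollection",
        "features": features,
        "properties": {
            "threshold_label": surface.attrs.get("threshold_label"),
            "threshold_ugL": surface.attrs.get("threshold_ugL"),
        },
    })
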