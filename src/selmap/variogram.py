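"""Empirical variography and exponential-model fitting.

The variogram (semivariance) gamma(h) is half the expected squared
difference between values separated by lag h. Lags here are great-circle
distances in km; on the sphere the exponential model is a permissible
covariance family, so it is the only model fitted:

    gamma(h) = c0 + c1 * (1 - exp(-h / a)),   h > 0;   gamma(0) = 0

with nugget c0 (spatially uncorrelated variance, including measurement
error), partial sill c1 (spatially correlated variance) and distance
parameter a (effective range ~ 3a).

Three per-bin estimators are provided. With d the pair differences in a
lag bin of N pairs:

* Matheron (method of moments):  sum(d^2) / (2 N)
* Cressie-Hawkins:               (mean |d|^(1/2))^4 / (2 (0.457 + 0.494/N))
* Dowd:                          2.198 * median(|d|)^2 / 2

The robust pair guard against spatial outliers inflating the semivariance;
Matheron is the more efficient estimator when the data are well behaved.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .geodesy import pairwise_lags, fold_bearing

__all__ = [
    "ESTIMATORS",
    "VariogramCloud",
    "EmpiricalVariogram",
    "ExponentialVariogramModel",
    "FitResult",
    "build_cloud",
    "default_bin_edges",
    "estimate",
    "directional_variograms",
    "fit_wls",
]

ESTIMATORS = ("matheron", "cressie_hawkins", "dowd")

#: Default minimum pair count per lag bin; thinner bins are dropped.
MIN_PAIRS = 30


@dataclass
class VariogramCloud:
    """All unordered pairs of EA samples: great-circle distance (km),
    bearing folded to [0, 180), and difference of mean serum Se (µg/L)."""
    dist: np.ndarray
    bearing: np.ndarray
    diff: np.ndarray

    def __len__(self):
        return self.dist.size


@dataclass
class EmpiricalVariogram:
    """Binned semivariance estimates.

    ``bins`` has columns lag (bin midpoint, km), mean_dist (mean pair
    distance in the bin, km), semivariance ((µg/L)^2) and n_pairs.
    ``bearing_class`` is None for the isotropic variogram, otherwise the
    class centre in degrees.
    """
    estimator: str
    bins: pd.DataFrame
    bearing_class: float | None = None

    def to_csv(self, path) -> None:
        self.bins.to_csv(path, index=False)


@dataclass(frozen=True)
class ExponentialVariogramModel:
    c0: float  # nugget, (µg/L)^2
    c1: float  # partial sill, (µg/L)^2
    a: float   # distance parameter, km

    def __post_init__(self):
        if self.c0 < 0 or self.c1 < 0 or self.a <= 0:
            raise ValueError("require c0 >= 0, c1 >= 0, a > 0")

    @property
    def sill(self) -> float:
        return self.c0 + self.c1

    def gamma(self, h):
        """Semivariance at lag h (km). gamma(0) is exactly 0; for h > 0
        the nugget appears as a discontinuity at the origin."""
        h = np.asarray(h, dtype=float)
        if (h < 0).any():
            raise ValueError("negative lag")
        g = self.c0 + self.c1 * (1.0 - np.exp(-h / self.a))
        g = np.where(h == 0.0, 0.0, g)
        return g if g.shape else float(g)

    def covariance(self, h):
        """Spatially correlated covariance c1*exp(-h/a); the nugget is a
        separate white-noise component at h = 0."""
        h = np.asarray(h, dtype=float)
        c = self.c1 * np.exp(-h / self.a)
        return c if c.shape else float(c)

    def to_json(self, **extra) -> str:
        return json.dumps({**asdict(self), **extra}, indent=2)


def build_cloud(ea: pd.DataFrame) -> VariogramCloud:
    """Variogram cloud from an EA-sample table (columns lat, lon, mean_se)."""
    if len(ea) < 2:
        raise ValueError("need at least 2 EA samples")
    lat = ea["lat"].to_numpy(dtype=float)
    lon = ea["lon"].to_numpy(dtype=float)
    z = ea["mean_se"].to_numpy(dtype=float)
    i, j, d, b = pairwise_lags(lat, lon)
    return VariogramCloud(dist=d, bearing=fold_bearing(b), diff=z[i] - z[j])


def default_bin_edges(cloud: VariogramCloud, n_bins: int = 25,
                      max_lag_fraction: float = 0.3) -> np.ndarray:
    """Equal-width lag bins from 0 to ``max_lag_fraction`` of the maximum
    pair distance (default 0.3, close to the bbox-diagonal/3 convention of
    gstat; longer lags add little model information but large
    single-realization fluctuation)."""
    return np.linspace(0.0, max_lag_fraction * float(cloud.dist.max()), n_bins + 1)


def _bin_semivariance(absdiff: np.ndarray, estimator: str) -> float:
    n = absdiff.size
    if estimator == "matheron":
        return float(np.sum(absdiff ** 2) / (2.0 * n))
    if estimator == "cressie_hawkins":
        m = float(np.mean(np.sqrt(absdiff)))
        return m ** 4 / (2.0 * (0.457 + 0.494 / n))
    if estimator == "dowd":
        return float(2.198 * np.median(absdiff) ** 2 / 2.0)
    raise ValueError(f"unknown estimator {estimator!r}")


def estimate(cloud: VariogramCloud, bin_edges=None, estimator: str = "matheron",
             min_pairs: int = MIN_PAIRS,
             bearing_class: float | None = None) -> EmpiricalVariogram:
    """Binned empirical variogram for one estimator.

    Zero-distance pairs never enter; bins with fewer than ``min_pairs``
    pairs are dropped with a warning (they are too noisy to constrain the
    fit).
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    if bin_edges is None:
        bin_edges = default_bin_edges(cloud)
    edges = np.asarray(bin_edges, dtype=float)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")

    keep = cloud.dist > 0
    d, ad = cloud.dist[keep], np.abs(cloud.diff[keep])
    which = np.digitize(d, edges) - 1  # bin k covers (edges[k], edges[k+1]]

    rows, dropped = [], 0
    for k in range(edges.size - 1):
        sel = which == k
        n = int(sel.sum())
        if n == 0:
            continue
        if n < min_pairs:
            dropped += 1
            continue
        rows.append({
            "lag": 0.5 * (edges[k] + edges[k + 1]),
            "mean_dist": float(d[sel].mean()),
            "semivariance": _bin_semivariance(ad[sel], estimator),
            "n_pairs": n,
        })
    if dropped:
        warnings.warn(f"dropped {dropped} lag bins with fewer than {min_pairs} pairs")
    return EmpiricalVariogram(estimator=estimator, bins=pd.DataFrame(rows),
                              bearing_class=bearing_class)


def directional_variograms(cloud: VariogramCloud, n_classes: int = 4,
                           bin_edges=None, estimator: str = "matheron",
                           min_pairs: int = MIN_PAIRS) -> list[EmpiricalVariogram]:
    """One empirical variogram per bearing class of width 180/n_classes
    degrees, centred at 0, 180/n, 2*180/n, ... (class 0 straddles north)."""
    if n_classes < 2:
        raise ValueError("need at least 2 bearing classes")
    width = 180.0 / n_classes
    centres = width * np.arange(n_classes)
    cls = np.mod(np.round(cloud.bearing / width).astype(int), n_classes)
    out = []
    for k, centre in enumerate(centres):
        sel = (cls == k) & ~np.isnan(cloud.bearing)
        sub = VariogramCloud(cloud.dist[sel], cloud.bearing[sel], cloud.diff[sel])
        if len(sub) < min_pairs:
            warnings.warn(f"bearing class {centre:.0f} deg has only {len(sub)} pairs")
        out.append(estimate(sub, bin_edges=bin_edges, estimator=estimator,
                            min_pairs=min_pairs, bearing_class=float(centre))
                   if len(sub) else
                   EmpiricalVariogram(estimator, pd.DataFrame(
                       columns=["lag", "mean_dist", "semivariance", "n_pairs"]),
                       bearing_class=float(centre)))
    return out


@dataclass
class FitResult:
    model: ExponentialVariogramModel
    objective: float
    converged: bool
    n_bins: int
    weight_scheme: str


def _wls_residuals(theta, h, gamma_hat, n_pairs, scheme):
    c0, c1, a = theta
    g = c0 + c1 * (1.0 - np.exp(-h / a))
    if scheme == "npairs":
        w = n_pairs.astype(float)
    elif scheme == "cressie":
        w = n_pairs / np.maximum(g, 1e-12) ** 2
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return np.sqrt(w) * (gamma_hat - g)


def fit_wls(emp: EmpiricalVariogram, init=None, weight_scheme: str = "cressie",
            n_starts: int = 3, lag_column: str = "mean_dist",
            max_a: float | None = None) -> FitResult:
    """Fit the exponential model to binned estimates by weighted least
    squares.

    Weights default to Cressie's n_k / gamma(h_k)^2 scheme, which
    emphasises the short lags that carry the nugget and distance-parameter
    information; plain pair-count weights are available as
    ``weight_scheme="npairs"``. The bounded optimiser (c0, c1 >= 0,
    0 < a <= max_a) is restarted from ``n_starts`` deterministic
    perturbations of the data-driven initial guess, keeping the lowest
    objective. ``max_a`` defaults to the largest fitted lag: beyond the
    observed lag span the data cannot inform the distance parameter, and
    an unbounded a admits a degenerate ridge (a and c1 growing together to
    mimic a straight line). Bins are positioned at the mean pair distance
    by default (``lag_column="lag"`` uses midpoints).
    """
    bins = emp.bins
    if len(bins) < 4:
        raise ValueError("need at least 4 usable lag bins to fit 3 parameters")
    h = bins[lag_column].to_numpy(dtype=float)
    gam = bins["semivariance"].to_numpy(dtype=float)
    npairs = bins["n_pairs"].to_numpy(dtype=float)

    if max_a is None:
        max_a = float(h[-1])
    sill0 = max(float(np.mean(gam[-max(3, len(gam) // 4):])), 1e-8)
    if init is None:
        c0_0 = min(max(float(gam[0]), 0.0), sill0)
        init = (c0_0, max(sill0 - c0_0, 1e-3 * sill0),
                min(max(float(h[-1]) / 3.0, 1e-6), max_a))
    if min(init[0], init[1]) < 0 or init[2] <= 0:
        raise ValueError("initial parameters must be non-negative (a > 0)")

    lb = np.array([0.0, 0.0, 1e-9])
    ub = np.array([np.inf, np.inf, max_a])
    starts = [np.clip(np.asarray(init, dtype=float), lb + 1e-12, ub)]
    rng = np.random.default_rng(1962)  # fixed: restarts are deterministic
    for _ in range(max(n_starts - 1, 0)):
        f = rng.uniform(0.3, 3.0, size=3)
        starts.append(np.clip(starts[0] * f, [0.0, 1e-8, 1e-6], ub))

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                _wls_residuals, x0,
                args=(h, gam, npairs, weight_scheme),
                bounds=(lb, ub),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise RuntimeError("weighted least-squares variogram fit did not converge")

    c0, c1, a = best.x
    model = ExponentialVariogramModel(c0=float(c0), c1=float(c1), a=float(a))
    return FitResult(model=model, objective=float(best.cost), converged=True,
                     n_bins=len(bins), weight_scheme=weight_scheme)
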