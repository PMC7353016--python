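"""Ordinary kriging on the sphere with cross-validation diagnostics.

Ordinary kriging (OK) is the best linear unbiased predictor under the
fitted variogram: the prediction at a target is a weighted sum of the data
with weights constrained to sum to one, obtained from the bordered system

    [ Gamma  1 ] [ lambda ]   [ gamma_0 ]
    [ 1^T    0 ] [   mu   ] = [    1    ]

where Gamma holds semivariances between data locations (zero diagonal) and
gamma_0 the semivariances between data and target, all on great-circle
distances. The kriging variance is lambda . gamma_0 + mu.

Model validity is judged by leave-one-out cross-validation: each squared
prediction error is standardized by its kriging variance (SSPE). If the
model is valid and errors are Gaussian each SSPE is ~ chi-square(1), whose
median is 0.455; the sampling interval of the median SSPE at the actual
data layout is obtained by Monte-Carlo simulation from the fitted model.
A global neighbourhood (every datum in every system) is used throughout —
feasible at a few hundred enumeration-area means and free of
search-neighbourhood artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve, cholesky
from scipy.stats import chi2

from .geodesy import great_circle_distance
from .variogram import ExponentialVariogramModel

__all__ = [
    "SSPE_MEDIAN_EXPECTED",
    "theoretical_median_sspe",
    "KrigingResult",
    "CrossValidationReport",
    "SelectionResult",
    "ok_solve",
    "ok_predict",
    "loo_cross_validate",
    "median_sspe_interval",
    "select_model",
]

#: Median of the chi-square(1) distribution: the expected median SSPE under
#: a valid variogram model with Gaussian kriging errors.
SSPE_MEDIAN_EXPECTED = float(chi2.ppf(0.5, df=1))


def theoretical_median_sspe() -> float:
    """Median of chi-square with 1 degree of freedom (~0.455)."""
    return SSPE_MEDIAN_EXPECTED


@dataclass(frozen=True)
class KrigingResult:
    lat: float
    lon: float
    prediction: float
    kriging_variance: float


@dataclass
class CrossValidationReport:
    """Leave-one-out results: per-site table (obs, pred, kriging variance,
    SSPE), the median SSPE, and — when a validity interval is supplied —
    a verdict on whether the model passes."""
    table: pd.DataFrame
    median_sspe: float
    interval: tuple[float, float] | None = None

    @property
    def valid(self) -> bool | None:
        if self.interval is None:
            return None
        lo, hi = self.interval
        return bool(lo <= self.median_sspe <= hi)


@dataclass
class SelectionResult:
    status: str                      # "selected" | "failed"
    chosen: str | None               # estimator name
    model: ExponentialVariogramModel | None
    audit: list[dict] = field(default_factory=list)


def _dist_matrix(lat1, lon1, lat2=None, lon2=None):
    if lat2 is None:
        lat2, lon2 = lat1, lon1
    return great_circle_distance(
        np.asarray(lat1)[:, None], np.asarray(lon1)[:, None],
        np.asarray(lat2)[None, :], np.asarray(lon2)[None, :])


def _collapse_duplicates(lat, lon, z):
    """Average observations at coincident coordinates (a duplicate with a
    zero nugget makes the OK system singular)."""
    df = pd.DataFrame({"lat": lat, "lon": lon, "z": z})
    g = df.groupby(["lat", "lon"], sort=False, as_index=False)["z"].mean()
    if len(g) < len(df):
        warnings.warn(f"collapsed {len(df) - len(g)} duplicate locations to their mean")
    return (g["lat"].to_numpy(), g["lon"].to_numpy(), g["z"].to_numpy())


def _bordered_matrix(model, lat, lon):
    n = lat.size
    gam = model.gamma(_dist_matrix(lat, lon))
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gam
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    return A


def _rhs(model, lat, lon, tlat, tlon):
    g0 = model.gamma(_dist_matrix(lat, lon, np.atleast_1d(tlat), np.atleast_1d(tlon)))
    b = np.vstack([g0, np.ones((1, g0.shape[1]))])
    return b


def _unpack_data(data):
    if isinstance(data, pd.DataFrame):
        return (data["lat"].to_numpy(dtype=float),
                data["lon"].to_numpy(dtype=float),
                data["mean_se"].to_numpy(dtype=float))
    lat, lon, z = data
    return (np.asarray(lat, dtype=float), np.asarray(lon, dtype=float),
            np.asarray(z, dtype=float))


def ok_solve(model: ExponentialVariogramModel, data, target_lat: float,
             target_lon: float):
    """Ordinary-kriging weights and Lagrange multiplier for one target.

    ``data`` is an EA-sample table (columns lat, lon, mean_se) or a
    (lat, lon, z) triple. Duplicate data locations with a zero nugget are
    rejected (singular system)."""
    lat, lon, z = _unpack_data(data)
    if lat.size < 2:
        raise ValueError("need at least 2 data points")
    if model.c0 == 0.0:
        D = _dist_matrix(lat, lon)
        iu = np.triu_indices(lat.size, k=1)
        dup = np.nonzero(D[iu] == 0.0)[0]
        if dup.size:
            i, j = iu[0][dup[0]], iu[1][dup[0]]
            raise ValueError(
                f"singular OK system: duplicate locations at rows {i} and {j} "
                "with zero nugget")
    A = _bordered_matrix(model, lat, lon)
    b = _rhs(model, lat, lon, target_lat, target_lon)[:, 0]
    x = solve(A, b, assume_a="sym")
    return x[:-1], float(x[-1])


def ok_predict(model: ExponentialVariogramModel, data, target_lat,
               target_lon) -> pd.DataFrame:
    """OK predictions and kriging variances at many targets.

    One factorization of the bordered matrix serves all targets. Returns a
    DataFrame (lat, lon, prediction, kriging_variance); tiny negative
    variances from rounding are clipped to zero."""
    lat, lon, z = _unpack_data(data)
    if lat.size < 2:
        raise ValueError("need at least 2 data points")
    lat, lon, z = _collapse_duplicates(lat, lon, z)
    tlat = np.atleast_1d(np.asarray(target_lat, dtype=float))
    tlon = np.atleast_1d(np.asarray(target_lon, dtype=float))

    A = _bordered_matrix(model, lat, lon)
    B = _rhs(model, lat, lon, tlat, tlon)
    X = solve(A, B, assume_a="sym")
    lam, mu = X[:-1, :], X[-1, :]
    pred = lam.T @ z
    var = np.einsum("ij,ij->j", lam, B[:-1, :]) + mu
    var = np.where((var < 0) & (var > -1e-8 * model.sill - 1e-12), 0.0, var)
    if (var < 0).any():
        raise RuntimeError("negative kriging variance beyond numerical tolerance")
    return pd.DataFrame({"lat": tlat, "lon": tlon,
                         "prediction": pred, "kriging_variance": var})


def _loo_weights(model, lat, lon):
    """Per-site LOO weight vectors and kriging variances.

    Row i of the returned (n, n) weight matrix predicts site i from the
    others (zero at position i); these depend only on the geometry and the
    model, so they can be reused across simulated fields."""
    n = lat.size
    gam = model.gamma(_dist_matrix(lat, lon))
    W = np.zeros((n, n))
    var = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        m = n - 1
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = gam[np.ix_(keep, keep)]
        A[:m, m] = 1.0
        A[m, :m] = 1.0
        A[m, m] = 0.0
        b = np.empty(m + 1)
        b[:m] = gam[keep, i]
        b[m] = 1.0
        x = solve(A, b, assume_a="sym")
        W[i, keep] = x[:m]
        var[i] = x[:m] @ b[:m] + x[m]
    return W, var


def loo_cross_validate(model: ExponentialVariogramModel, data,
                       interval: tuple[float, float] | None = None
                       ) -> CrossValidationReport:
    """Leave-one-out cross-validation of a variogram model.

    Each site is predicted from all the others by OK; the squared error is
    standardized by the kriging variance (SSPE). Requires >= 10 sites."""
    lat, lon, z = _unpack_data(data)
    if lat.size < 10:
        raise ValueError("need at least 10 data points for cross-validation")
    lat, lon, z = _collapse_duplicates(lat, lon, z)
    W, var = _loo_weights(model, lat, lon)
    pred = W @ z
    if (var <= 0).any():
        raise RuntimeError("zero kriging variance in cross-validation; "
                           "SSPE undefined")
    sspe = (z - pred) ** 2 / var
    table = pd.DataFrame({"lat": lat, "lon": lon, "observed": z,
                          "predicted": pred, "kriging_variance": var,
                          "sspe": sspe})
    return CrossValidationReport(table=table,
                                 median_sspe=float(np.median(sspe)),
                                 interval=interval)


def median_sspe_interval(model: ExponentialVariogramModel, lat, lon,
                         n_sim: int = 1000, seed: int = 0,
                         jitter: float = 1e-8) -> tuple[float, float]:
    """95% Monte-Carlo interval for the median SSPE at the given layout.

    Simulates ``n_sim`` Gaussian fields from the model at the data
    locations, cross-validates each with precomputed LOO weights, and
    returns the 2.5th/97.5th percentiles of the median SSPE. The interval
    is specific to the data configuration, not a universal constant,
    though it always brackets the chi-square(1) median 0.455 for a healthy
    layout."""
    if n_sim < 500:
        raise ValueError("n_sim must be at least 500 for a stable interval")
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    n = lat.size
    W, var = _loo_weights(model, lat, lon)
    D = _dist_matrix(lat, lon)
    C = model.covariance(D) + (model.c0 + jitter * model.sill) * np.eye(n)
    L = cholesky(C, lower=True)
    rng = np.random.default_rng(seed)
    Z = L @ rng.standard_normal((n, n_sim))
    err = Z - W @ Z
    medians = np.median(err ** 2 / var[:, None], axis=0)
    lo, hi = np.percentile(medians, [2.5, 97.5])
    return float(lo), float(hi)


def select_model(candidates: dict, data, n_sim: int = 1000, seed: int = 0
                 ) -> SelectionResult:
    """Variogram-model selection by cross-validation.

    ``candidates`` maps estimator name to fitted model and must include
    ``"matheron"``. The Matheron fit is accepted outright if its median
    SSPE lies inside its Monte-Carlo validity interval (it is the most
    efficient estimator, so the robust alternatives are then not even
    cross-validated). Otherwise the robust fits are cross-validated and,
    among those whose median falls in their own interval, the one closest
    to 0.455 is chosen; if none qualifies the selection fails explicitly.
    """
    if "matheron" not in candidates:
        raise ValueError("candidates must include the Matheron fit")
    lat, lon, z = _unpack_data(data)
    audit = []

    def evaluate(name):
        model = candidates[name]
        interval = median_sspe_interval(model, lat, lon, n_sim=n_sim, seed=seed)
        report = loo_cross_validate(model, (lat, lon, z), interval=interval)
        audit.append({"estimator": name, "median_sspe": report.median_sspe,
                      "interval": interval, "valid": report.valid})
        return report

    report = evaluate("matheron")
    if report.valid:
        return SelectionResult("selected", "matheron", candidates["matheron"], audit)

    robust = [k for k in ("cressie_hawkins", "dowd") if k in candidates]
    best_name, best_gap = None, np.inf
    for name in robust:
        rep = evaluate(name)
        gap = abs(rep.median_sspe - SSPE_MEDIAN_EXPECTED)
        if rep.valid and gap < best_gap:
            best_name, best_gap = name, gap
    if best_name is None:
        return SelectionResult("failed", None, None, audit)
    return SelectionResult("selected", best_name, candidates[best_name], audit)
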