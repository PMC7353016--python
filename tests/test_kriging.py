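"""Ordinary kriging, LOO cross-validation and model selection."""

import numpy as np
import pandas as pd
import pytest

from selmap import geodesy, kriging, simulate
from selmap.variogram import ExponentialVariogramModel


@pytest.fixture
def no_nugget_model():
    return ExponentialVariogramModel(c0=0.0, c1=25.0, a=150.0)


def _random_data(rng, n, model, mean=100.0):
    cfg = simulate.SimulationConfig(seed=int(rng.integers(2 ** 31)), n_eas=n)
    locs = simulate.simulate_ea_locations(cfg)
    lat = locs["lat"].to_numpy()
    lon = locs["lon"].to_numpy()
    z = simulate.simulate_grf(model, lat, lon, mean, rng)
    return lat, lon, z


class TestOkSolve:
    def test_weights_sum_to_one(self, field_model, rng):
        lat, lon, z = _random_data(rng, 25, field_model)
        for tlat, tlon in [(9.0, 40.0), (3.5, 33.5), (14.9, 47.9)]:
            w, mu = kriging.ok_solve(field_model, (lat, lon, z), tlat, tlon)
            assert abs(w.sum() - 1.0) < 1e-10

    def test_exact_interpolation_weight(self, no_nugget_model, rng):
        lat, lon, z = _random_data(rng, 10, no_nugget_model)
        w, mu = kriging.ok_solve(no_nugget_model, (lat, lon, z), lat[3], lon[3])
        expect = np.zeros(10)
        expect[3] = 1.0
        assert np.allclose(w, expect, atol=1e-8)

    def test_symmetric_pair_equal_weights(self, field_model):
        # two data points symmetric about the target
        lat, lon = np.array([10.0, 10.0]), np.array([38.0, 42.0])
        w, _ = kriging.ok_solve(field_model, (lat, lon, np.array([90.0, 110.0])),
                                10.0, 40.0)
        assert np.allclose(w, [0.5, 0.5], atol=1e-10)

    def test_matches_dense_linear_algebra_oracle(self, field_model, rng):
        """5-point system solved independently with raw numpy."""
        lat, lon, z = _random_data(rng, 5, field_model)
        tlat, tlon = 8.0, 41.0
        w, mu = kriging.ok_solve(field_model, (lat, lon, z), tlat, tlon)
        A = np.zeros((6, 6))
        for i in range(5):
            for j in range(5):
                if i != j:
                    d = geodesy.great_circle_distance(lat[i], lon[i], lat[j], lon[j])
                    A[i, j] = field_model.gamma(d)
        A[:5, 5] = 1.0
        A[5, :5] = 1.0
        b = np.array([field_model.gamma(
            geodesy.great_circle_distance(lat[i], lon[i], tlat, tlon))
            for i in range(5)] + [1.0])
        x = np.linalg.solve(A, b)
        assert np.allclose(w, x[:5], atol=1e-9)
        assert mu == pytest.approx(x[5], abs=1e-9)

    def test_duplicate_locations_zero_nugget_rejected(self, no_nugget_model):
        lat = np.array([5.0, 5.0, 7.0])
        lon = np.array([40.0, 40.0, 41.0])
        with pytest.raises(ValueError, match="duplicate"):
            kriging.ok_solve(no_nugget_model, (lat, lon, np.ones(3)), 6.0, 40.5)


class TestOkPredict:
    def test_constant_data_passes_through(self, field_model, rng):
        lat, lon, _ = _random_data(rng, 15, field_model)
        z = np.full(15, 77.7)
        out = kriging.ok_predict(field_model, (lat, lon, z),
                                 np.array([5.0, 12.0]), np.array([35.0, 45.0]))
        assert np.allclose(out["prediction"], 77.7, atol=1e-8)

    def test_exact_interpolation_at_datum(self, no_nugget_model, rng):
        lat, lon, z = _random_data(rng, 12, no_nugget_model)
        out = kriging.ok_predict(no_nugget_model, (lat, lon, z), lat[:3], lon[:3])
        assert np.allclose(out["prediction"], z[:3], atol=1e-6)
        assert np.allclose(out["kriging_variance"], 0.0, atol=1e-6)

    def test_constant_shift_equivariance(self, field_model, rng):
        lat, lon, z = _random_data(rng, 20, field_model)
        t = (np.array([9.0]), np.array([40.0]))
        base = kriging.ok_predict(field_model, (lat, lon, z), *t)
        shifted = kriging.ok_predict(field_model, (lat, lon, z + 55.0), *t)
        assert shifted["prediction"][0] == pytest.approx(base["prediction"][0] + 55.0)
        assert shifted["kriging_variance"][0] == pytest.approx(
            base["kriging_variance"][0])

    def test_far_field_tends_to_mean_with_full_sill(self, field_model, rng):
        """Far beyond the correlation range the prediction approaches the
        generalized mean of the data and the variance the sill level;
        checked against a direct dense solve at h ~ 20a."""
        lat = np.array([5.0, 5.5, 6.0, 6.5, 7.0])
        lon = np.array([34.0, 35.0, 34.5, 35.5, 34.2])
        z = np.array([90.0, 110.0, 95.0, 105.0, 100.0])
        # ~2900 km east: every lag >> 3a
        out = kriging.ok_predict(field_model, (lat, lon, z),
                                 np.array([6.0]), np.array([60.0]))
        w, mu = kriging.ok_solve(field_model, (lat, lon, z), 6.0, 60.0)
        assert out["prediction"][0] == pytest.approx(float(w @ z), abs=1e-9)
        assert z.min() <= out["prediction"][0] <= z.max()
        assert out["kriging_variance"][0] > field_model.sill

    def test_variance_nonnegative_and_bounded(self, field_model, rng):
        lat, lon, z = _random_data(rng, 40, field_model)
        grid_lat = rng.uniform(3, 15, 50)
        grid_lon = rng.uniform(33, 48, 50)
        out = kriging.ok_predict(field_model, (lat, lon, z), grid_lat, grid_lon)
        assert (out["kriging_variance"] >= 0).all()
        assert (out["kriging_variance"] <= 2 * field_model.sill).all()

    def test_duplicates_collapsed_with_warning(self, field_model):
        lat = np.array([5.0, 5.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0])
        lon = np.full(10, 40.0)
        z = np.arange(10.0)
        with pytest.warns(UserWarning, match="collapsed"):
            out = kriging.ok_predict(field_model, (lat, lon, z),
                                     np.array([6.0]), np.array([40.0]))
        assert np.isfinite(out["prediction"][0])


class TestLooCrossValidation:
    def test_two_point_closed_form(self, field_model):
        """With one datum left, OK predicts that datum with variance
        2 gamma(d); SSPE follows by hand."""
        lat = np.array([8.0, 9.0])
        lon = np.array([40.0, 40.0])
        z = np.array([95.0, 105.0])
        W, var = kriging._loo_weights(field_model, lat, lon)
        d = geodesy.great_circle_distance(8, 40, 9, 40)
        g = field_model.gamma(d)
        assert np.allclose(W, [[0, 1], [1, 0]], atol=1e-12)
        assert np.allclose(var, 2 * g, atol=1e-9)
        sspe = (z[0] - z[1]) ** 2 / (2 * g)
        err = z - W @ z
        assert np.allclose(err ** 2 / var, sspe, atol=1e-9)

    def test_scale_equivariance_of_sspe(self, field_model, rng):
        lat, lon, z = _random_data(rng, 15, field_model)
        rep1 = kriging.loo_cross_validate(field_model, (lat, lon, z))
        k2 = 9.0
        scaled = ExponentialVariogramModel(field_model.c0 * k2,
                                           field_model.c1 * k2, field_model.a)
        zbar = z.mean()
        rep2 = kriging.loo_cross_validate(scaled, (lat, lon, zbar + 3.0 * (z - zbar)))
        assert np.allclose(rep1.table["sspe"], rep2.table["sspe"], atol=1e-8)

    def test_median_matches_table(self, field_model, rng):
        lat, lon, z = _random_data(rng, 20, field_model)
        rep = kriging.loo_cross_validate(field_model, (lat, lon, z))
        assert rep.median_sspe == pytest.approx(float(rep.table["sspe"].median()))
        assert (rep.table["sspe"] >= 0).all()

    def test_minimum_sites(self, field_model):
        with pytest.raises(ValueError):
            kriging.loo_cross_validate(
                field_model, (np.arange(5.0), np.arange(5.0) + 40, np.ones(5)))


class TestMedianSspeInterval:
    def test_contains_theoretical_median_and_deterministic(self, field_model, rng):
        lat, lon, _ = _random_data(rng, 40, field_model)
        i1 = kriging.median_sspe_interval(field_model, lat, lon, n_sim=500, seed=9)
        i2 = kriging.median_sspe_interval(field_model, lat, lon, n_sim=500, seed=9)
        assert i1 == i2
        assert i1[0] < kriging.SSPE_MEDIAN_EXPECTED < i1[1]

    def test_interval_narrows_with_more_sites(self, field_model, rng):
        widths = {n: [] for n in (30, 120)}
        for rep in range(3):
            for n in widths:
                lat, lon, _ = _random_data(rng, n, field_model)
                lo, hi = kriging.median_sspe_interval(field_model, lat, lon,
                                                      n_sim=500, seed=rep)
                widths[n].append(hi - lo)
        assert np.mean(widths[120]) < np.mean(widths[30])

    def test_n_sim_floor(self, field_model, rng):
        lat, lon, _ = _random_data(rng, 15, field_model)
        with pytest.raises(ValueError):
            kriging.median_sspe_interval(field_model, lat, lon, n_sim=100)


class TestSelectModel:
    def test_valid_matheron_short_circuits(self, field_model, rng):
        lat, lon, z = _random_data(rng, 60, field_model)
        candidates = {"matheron": field_model,
                      "cressie_hawkins": field_model, "dowd": field_model}
        sel = kriging.select_model(candidates, (lat, lon, z), n_sim=500, seed=2)
        assert sel.status == "selected"
        # true model should validate; robust candidates never cross-validated
        assert sel.chosen == "matheron"
        assert len(sel.audit) == 1

    def test_matheron_required(self, field_model, rng):
        lat, lon, z = _random_data(rng, 20, field_model)
        with pytest.raises(ValueError):
            kriging.select_model({"dowd": field_model}, (lat, lon, z))

    def test_closest_to_theoretical_median_wins(self, field_model, rng, monkeypatch):
        """Forced medians: Matheron invalid, Dowd at 0.46, CH at 0.60 with
        a validity interval (0.34, 0.57) -> Dowd chosen."""
        lat, lon, z = _random_data(rng, 20, field_model)
        medians = {"matheron": 0.90, "cressie_hawkins": 0.60, "dowd": 0.46}
        candidates = {k: ExponentialVariogramModel(2.51 + i, 26.23, 132.8)
                      for i, k in enumerate(medians)}
        by_model = {id(m): medians[k] for k, m in candidates.items()}

        monkeypatch.setattr(kriging, "median_sspe_interval",
                            lambda model, *a, **k: (0.34, 0.57))
        monkeypatch.setattr(
            kriging, "loo_cross_validate",
            lambda model, data, interval=None: kriging.CrossValidationReport(
                table=pd.DataFrame({"sspe": [by_model[id(model)]]}),
                median_sspe=by_model[id(model)], interval=interval))
        sel = kriging.select_model(candidates, (lat, lon, z), n_sim=500, seed=0)
        assert sel.status == "selected" and sel.chosen == "dowd"
        assert len(sel.audit) == 3

    def test_all_invalid_fails_explicitly(self, field_model, rng, monkeypatch):
        lat, lon, z = _random_data(rng, 20, field_model)
        candidates = {k: ExponentialVariogramModel(2.51, 26.23, 132.8 + i)
                      for i, k in enumerate(("matheron", "cressie_hawkins", "dowd"))}
        monkeypatch.setattr(kriging, "median_sspe_interval",
                            lambda model, *a, **k: (0.34, 0.57))
        monkeypatch.setattr(
            kriging, "loo_cross_validate",
            lambda model, data, interval=None: kriging.CrossValidationReport(
                table=pd.DataFrame({"sspe": [2.0]}), median_sspe=2.0,
                interval=interval))
        sel = kriging.select_model(candidates, (lat, lon, z), n_sim=500, seed=0)
        assert sel.status == "failed" and sel.model is None
        assert [a["estimator"] for a in sel.audit] == \
            ["matheron", "cressie_hawkins", "dowd"]
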