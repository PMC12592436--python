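"""Ensemble skill-and-independence weighting."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from cryolight.forcing import ForcingField
from cryolight.weighting import (
    Diagnostics,
    average_realizations,
    compute_diagnostics,
    compute_distances,
    compute_weights,
    weighted_ensemble_mean,
)


def _field(values, lat=None, lon=None, start="1980-01"):
    lat = np.array([66.0, 70.0]) if lat is None else lat
    lon = np.array([0.0, 10.0]) if lon is None else lon
    n = values.shape[0]
    months = pd.period_range(start, periods=n, freq="M")
    time = pd.DatetimeIndex([p.to_timestamp() + pd.Timedelta(days=14) for p in months])
    da = xr.DataArray(values, dims=("time", "lat", "lon"),
                      coords={"time": time, "lat": lat, "lon": lon})
    return ForcingField("tos", da)


class TestDiagnostics:
    def test_constant_field(self):
        d = compute_diagnostics(_field(np.full((240, 2, 2), 4.5)))
        np.testing.assert_allclose(d.climatology.values, 4.5)
        np.testing.assert_allclose(d.trend.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(d.std.values, 0.0, atol=1e-12)

    def _calendar_years(self, n, start="1980-01"):
        months = pd.period_range(start, periods=n, freq="M")
        time = pd.DatetimeIndex([p.to_timestamp() + pd.Timedelta(days=14) for p in months])
        return np.asarray(time.year + (time.month - 0.5) / 12.0, dtype=float)

    def test_pure_linear_trend(self):
        n = 240
        t_years = self._calendar_years(n)
        vals = (2.0 + 0.03 * (t_years - t_years[0]))[:, None, None] * np.ones((1, 2, 2))
        d = compute_diagnostics(_field(vals))
        np.testing.assert_allclose(d.trend.values, 0.03, rtol=1e-6)
        np.testing.assert_allclose(d.std.values, 0.0, atol=1e-9)

    def test_sinusoid_plus_trend_recovered(self):
        n = 360
        t_years = self._calendar_years(n)
        series = 1.0 + 0.02 * (t_years - t_years[0]) + 0.5 * np.sin(2 * np.pi * t_years)
        vals = series[:, None, None] * np.ones((1, 2, 2))
        d = compute_diagnostics(_field(vals))
        np.testing.assert_allclose(d.trend.values, 0.02, rtol=0.01)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            compute_diagnostics(_field(np.zeros((60, 2, 2))))


def _diag(clim, trend=0.0, std=0.0, lat=None):
    lat = np.array([66.0, 70.0]) if lat is None else lat
    lon = np.array([0.0, 10.0])
    coords = {"lat": lat, "lon": lon}

    def da(v):
        return xr.DataArray(np.broadcast_to(np.asarray(v, float), (2, 2)).copy(),
                            coords=coords, dims=("lat", "lon"))

    return Diagnostics(climatology=da(clim), trend=da(trend), std=da(std))


class TestDistances:
    def test_perfect_model_has_zero_distance(self):
        obs = _diag(3.0, 0.01, 0.4)
        d, s, ids = compute_distances({"a": _diag(3.0, 0.01, 0.4), "b": _diag(4.0, 0.02, 0.5)}, obs)
        assert d[ids.index("a")] == pytest.approx(0.0, abs=1e-12)
        assert d[ids.index("b")] > 0.0

    def test_identical_models_have_zero_separation(self):
        obs = _diag(3.0)
        d, s, ids = compute_distances({"a": _diag(5.0), "b": _diag(5.0)}, obs)
        assert s[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_cell_rmse_by_hand(self):
        # model differs from obs by +1 at 66N and -1 at 70N in climatology only;
        # area weights are cos(lat), so the RMSE is sqrt(mean of 1) = 1
        obs = _diag([[3.0, 3.0], [3.0, 3.0]])
        model = _diag([[4.0, 4.0], [2.0, 2.0]])
        d, _, _ = compute_distances({"a": model, "b": _diag(3.5)}, obs)
        # raw climatology RMSE for 'a' is exactly 1 (squared error 1 in every
        # cell regardless of the cos-latitude weights); for 'b' it is 0.5.
        # Each diagnostic is divided by its ensemble median and the three
        # diagnostics averaged; trend/std contribute zero here.
        raw_a, raw_b = 1.0, 0.5
        med = np.median([raw_a, raw_b])
        assert d[0] == pytest.approx((raw_a / med) / 3.0)
        assert d[1] == pytest.approx((raw_b / med) / 3.0)

    def test_realization_averaging(self):
        diags = {("m", "r1"): _diag(2.0), ("m", "r2"): _diag(4.0), ("n", "r1"): _diag(3.0)}
        merged = average_realizations(diags)
        np.testing.assert_allclose(merged["m"].climatology.values, 3.0)
        assert set(merged) == {"m", "n"}


class TestWeights:
    def test_single_perfect_model(self):
        w = compute_weights(np.array([0.0]), np.zeros((1, 1)))
        assert w[0] == pytest.approx(1.0)

    def test_identical_models_split_evenly(self):
        m = 4
        d = np.zeros(m)
        s = np.zeros((m, m))
        raw = compute_weights(d, s, sigma_d=1.0, sigma_s=1.0, normalize=False)
        np.testing.assert_allclose(raw, 1.0 / m)
        w = compute_weights(d, s, sigma_d=1.0, sigma_s=1.0)
        np.testing.assert_allclose(w, 1.0 / m)

    def test_performance_decay_scale(self):
        # a lone model at D = sigma_D with no close neighbors: raw w = e^-1
        d = np.array([1.0, 50.0])
        s = np.array([[0.0, 1e6], [1e6, 0.0]])
        raw = compute_weights(d, s, sigma_d=1.0, sigma_s=1.0, normalize=False)
        assert raw[0] == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_duplicate_model_penalized(self):
        base_d = np.array([0.5, 0.8])
        base_s = np.array([[0.0, 2.0], [2.0, 0.0]])
        w_unique = compute_weights(base_d, base_s, sigma_d=1.0, sigma_s=1.0)
        # duplicate the first model
        d3 = np.array([0.5, 0.5, 0.8])
        s3 = np.array([[0.0, 0.0, 2.0], [0.0, 0.0, 2.0], [2.0, 2.0, 0.0]])
        w_dup = compute_weights(d3, s3, sigma_d=1.0, sigma_s=1.0)
        assert w_dup[0] < w_unique[0]
        # but the duplicated pair together carries roughly the original share
        assert w_dup[0] + w_dup[1] == pytest.approx(w_unique[0], rel=0.25)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(np.array([0.5]), np.zeros((1, 1)), sigma_d=-1.0, sigma_s=1.0)


class TestWeightedMean:
    def _fields(self):
        coords = {"lat": [66.0, 70.0], "lon": [0.0, 10.0]}
        a = xr.DataArray(np.full((2, 2), 1.0), coords=coords, dims=("lat", "lon"))
        b = xr.DataArray(np.full((2, 2), 5.0), coords=coords, dims=("lat", "lon"))
        return a, b

    def test_equal_weights_are_arithmetic_mean(self):
        a, b = self._fields()
        out = weighted_ensemble_mean([a, b], np.array([0.5, 0.5]))
        np.testing.assert_allclose(out.values, 3.0)

    def test_one_hot_selects_model(self):
        a, b = self._fields()
        out = weighted_ensemble_mean([a, b], np.array([0.0, 1.0]))
        np.testing.assert_allclose(out.values, b.values)

    def test_quarter_three_quarter_blend(self):
        a, b = self._fields()
        out = weighted_ensemble_mean([a, b], np.array([0.25, 0.75]))
        np.testing.assert_allclose(out.values, 0.25 * 1.0 + 0.75 * 5.0)

    def test_mean_bounded_by_member_range(self):
        a, b = self._fields()
        out = weighted_ensemble_mean([a, b], np.array([0.3, 0.7]))
        assert float(out.min()) >= 1.0 and float(out.max()) <= 5.0

    def test_mismatched_weights_rejected(self):
        a, b = self._fields()
        with pytest.raises(ValueError):
            weighted_ensemble_mean([a, b], np.array([1.0]))
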