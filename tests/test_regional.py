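"""Area weighting, regional series, anomaly tables, threshold durations."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from cryolight.regional import (
    EARTH_RADIUS_KM,
    area_above_light,
    area_weighted_mean,
    cell_area,
    decadal_monthly_anomaly,
    lme_mask,
    months_above_threshold,
    open_water_fraction,
    rolling_mean,
)


class TestCellArea:
    def test_pole_has_zero_area(self):
        assert cell_area(90.0) == pytest.approx(0.0, abs=1e-9)

    def test_cosine_ratio(self):
        assert cell_area(60.0) / cell_area(0.0) == pytest.approx(0.5)

    def test_one_degree_cell_at_60N(self):
        expected = EARTH_RADIUS_KM**2 * np.deg2rad(1.0) ** 2 * 0.5
        assert cell_area(60.0) == pytest.approx(expected)
        assert cell_area(60.0) == pytest.approx(6182.0, rel=1e-3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cell_area(95.0)


def _grid_field(values, lat, lon):
    return xr.DataArray(values, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))


class TestAreaWeightedMean:
    def test_constant(self):
        f = _grid_field(np.full((3, 4), 2.5), [60.0, 61.0, 62.0], [0.0, 1.0, 2.0, 3.0])
        mask = _grid_field(np.ones((3, 4), bool), [60.0, 61.0, 62.0], [0.0, 1.0, 2.0, 3.0])
        assert float(area_weighted_mean(f, mask)) == pytest.approx(2.5)

    def test_equal_latitude_cells_average_evenly(self):
        f = _grid_field(np.array([[0.0, 2.0]]), [65.0], [0.0, 1.0])
        mask = _grid_field(np.ones((1, 2), bool), [65.0], [0.0, 1.0])
        assert float(area_weighted_mean(f, mask)) == pytest.approx(1.0)

    def test_cosine_weighting_across_latitudes(self):
        f = _grid_field(np.array([[1.0], [0.0]]), [60.0, 80.0], [0.0])
        mask = _grid_field(np.ones((2, 1), bool), [60.0, 80.0], [0.0])
        w60, w80 = np.cos(np.deg2rad(60.0)), np.cos(np.deg2rad(80.0))
        assert float(area_weighted_mean(f, mask)) == pytest.approx(w60 / (w60 + w80))
        assert float(area_weighted_mean(f, mask)) == pytest.approx(0.7422, abs=5e-4)

    def test_empty_region_rejected(self):
        f = _grid_field(np.full((1, 1), np.nan), [65.0], [0.0])
        mask = _grid_field(np.ones((1, 1), bool), [65.0], [0.0])
        with pytest.raises(ValueError):
            area_weighted_mean(f, mask)


class TestLmeMasks:
    def test_boxes_nonempty_and_in_domain(self):
        lat = np.arange(60.0, 86.0)
        lon = np.arange(0.0, 360.0)
        for name, center in (("barents", 75.0), ("northern-bering-chukchi", 69.5)):
            rm = lme_mask(name, lat, lon)
            assert bool(rm.mask.any())
            assert rm.center_lat == center
            lats_in = lat[rm.mask.any("lon").values]
            assert lats_in.min() >= 60.0 and lats_in.max() <= 85.0

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            lme_mask("laptev", np.arange(60.0, 86.0), np.arange(0.0, 360.0))


class TestRollingMean:
    def test_constant_invariant(self):
        s = pd.Series(3.0, index=pd.date_range("2000", periods=20, freq="YS"))
        np.testing.assert_allclose(rolling_mean(s).values, 3.0)

    def test_linear_preserved_in_interior(self):
        s = pd.Series(np.arange(20.0), index=pd.date_range("2000", periods=20, freq="YS"))
        out = rolling_mean(s, 5)
        np.testing.assert_allclose(out.values[2:-2], s.values[2:-2])

    def test_step_function_ramp(self):
        vals = np.array([0.0] * 5 + [1.0] * 5)
        s = pd.Series(vals, index=pd.date_range("2000", periods=10, freq="YS"))
        out = rolling_mean(s, 5)
        # center of the 5-point window crossing the step: 1/5, 2/5, 3/5, 4/5
        np.testing.assert_allclose(out.values[3:7], [0.2, 0.4, 0.6, 0.8])


def _monthly_series(values, start="1980-01"):
    months = pd.period_range(start, periods=len(values), freq="M")
    idx = pd.DatetimeIndex([p.to_timestamp() + pd.Timedelta(days=14) for p in months])
    return pd.Series(values, index=idx)


class TestDecadalAnomaly:
    def test_identical_to_baseline_is_zero(self):
        vals = np.tile(np.arange(12.0), 2100 - 1980 + 1)
        s = _monthly_series(vals)
        table = decadal_monthly_anomaly(s)
        anomaly_cols = [c for c in table.columns if c.endswith("s")]
        for c in anomaly_cols:
            np.testing.assert_allclose(table[c].values, 0.0, atol=1e-12)

    def test_uniform_shift_after_2050(self):
        n = (2100 - 1980 + 1) * 12
        s = _monthly_series(np.zeros(n))
        idx = pd.DatetimeIndex(s.index)
        s[idx.year >= 2050] = 1.0
        table = decadal_monthly_anomaly(s)
        np.testing.assert_allclose(table["2060s"].values, 1.0)
        np.testing.assert_allclose(table["2010s"].values, 0.0, atol=1e-12)

    def test_linear_trend_closed_form(self):
        n = (2100 - 1980 + 1) * 12
        s = _monthly_series(np.zeros(n))
        idx = pd.DatetimeIndex(s.index)
        s[:] = 0.02 * (idx.year - 1990)
        table = decadal_monthly_anomaly(s)
        np.testing.assert_allclose(table["2080s"].values, 0.02 * (2084.5 - 1990.0), rtol=1e-3)

    def test_missing_baseline_rejected(self):
        s = _monthly_series(np.zeros(120), start="2050-01")
        with pytest.raises(ValueError):
            decadal_monthly_anomaly(s)


class TestMonthsAboveThreshold:
    def _year(self, month_values):
        return _monthly_series(np.asarray(month_values, float), start="1990-01")

    def test_all_above(self):
        s = self._year([2.0] * 12)
        out = months_above_threshold(s, 1.0, "winter-spring")
        assert out.loc[1990] == pytest.approx(6.0)

    def test_none_above(self):
        s = self._year([0.0] * 12)
        assert months_above_threshold(s, 1.0, "winter-spring").loc[1990] == 0.0

    def test_interpolated_crossing(self):
        # Jan-Mar dark, Apr-Jun bright: the crossing interval contributes the
        # interpolated fraction, the edges half a month each
        s = self._year([0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        out = months_above_threshold(s, 0.5, "winter-spring")
        assert out.loc[1990] == pytest.approx(0.5 + 1.0 + 1.0 + 0.5)
        out_low = months_above_threshold(s, 0.25, "winter-spring")
        assert out_low.loc[1990] == pytest.approx(0.75 + 1.0 + 1.0 + 0.5)

    def test_monotone_under_pointwise_increase(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 2, 12)
        s1 = self._year(base)
        s2 = self._year(base + 0.3)
        for half in ("winter-spring", "summer-fall"):
            assert (
                months_above_threshold(s2, 1.0, half).loc[1990]
                >= months_above_threshold(s1, 1.0, half).loc[1990]
            )

    def test_incomplete_year_skipped(self):
        s = _monthly_series(np.ones(10), start="1990-01")
        out = months_above_threshold(s, 0.5, "winter-spring")
        assert 1990 not in out.index


class TestOpenWaterAndLightArea:
    def _mask(self, lat, lon):
        return _grid_field(np.ones((len(lat), len(lon)), bool), lat, lon)

    def test_all_ice_zero_fraction(self):
        sic = _grid_field(np.ones((2, 2)), [65.0, 66.0], [0.0, 1.0])
        assert float(open_water_fraction(sic, self._mask([65.0, 66.0], [0.0, 1.0]))) == 0.0

    def test_all_open_full_fraction(self):
        sic = _grid_field(np.zeros((2, 2)), [65.0, 66.0], [0.0, 1.0])
        assert float(open_water_fraction(sic, self._mask([65.0, 66.0], [0.0, 1.0]))) == 1.0

    def test_half_open_equal_latitude(self):
        sic = _grid_field(np.array([[0.0, 1.0]]), [65.0], [0.0, 1.0])
        assert float(open_water_fraction(sic, self._mask([65.0], [0.0, 1.0]))) == pytest.approx(0.5)

    def test_lit_area_bounded_by_region_area(self):
        lat, lon = [65.0, 66.0], [0.0, 1.0]
        par = _grid_field(np.array([[5.0, 0.0], [5.0, 5.0]]), lat, lon)
        mask = self._mask(lat, lon)
        lit = float(area_above_light(par, mask, 0.1))
        total = float(sum(cell_area(la) * len(lon) for la in lat))
        assert 0.0 < lit < total
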