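"""Synthetic watershed generators: terrain, weather, NDVI, litter."""

import numpy as np
import pandas as pd
import pytest

from soilscape.ansai import ANSAI_MEAN_ANNUAL_MM, ansai_climate_table, \
    ansai_weather_params
from soilscape.grid import DomainError, GridDomain
from soilscape.synthetic import (
    CORNFIELD_LITTER_CURVE,
    NdviLitterCurve,
    ParameterError,
    WeatherParams,
    generate_dem,
    generate_landcover,
    generate_ndvi,
    generate_weather,
    ndvi_to_litter,
)
from soilscape.terrain import route_flow


class TestGenerateDem:
    def test_zero_relief_is_uniform(self):
        dem = generate_dem(GridDomain(8, 8), "natural", relief=0.0, seed=1)
        assert np.ptp(dem.elevation) == 0.0

    def test_seeded_determinism(self):
        a = generate_dem(GridDomain(16, 16), "natural", relief=15, seed=9)
        b = generate_dem(GridDomain(16, 16), "natural", relief=15, seed=9)
        assert np.array_equal(a.elevation, b.elevation)

    def test_different_seeds_differ(self):
        a = generate_dem(GridDomain(16, 16), "natural", relief=15, seed=1)
        b = generate_dem(GridDomain(16, 16), "natural", relief=15, seed=2)
        assert not np.array_equal(a.elevation, b.elevation)

    def test_every_cell_drains_to_outlet(self):
        """Exhaustive D8 walk: every cell's receiver chain ends at the
        outlet after pit filling."""
        dem = generate_dem(GridDomain(64, 64), "natural", relief=15, seed=5)
        net = route_flow(dem)
        out_r, out_c = dem.domain.outlet
        outlet_idx = out_r * 64 + out_c
        for i in range(net.n_cells):
            j, hops = i, 0
            while net.receiver[j] >= 0:
                j = net.receiver[j]
                hops += 1
                assert hops <= net.n_cells, "cycle in receiver graph"
            assert j == outlet_idx

    def test_consolidated_parcels_flat_and_stepped(self, consolidated_dem):
        dom = consolidated_dem.domain
        lc = generate_landcover(dom, "consolidated")
        eta = consolidated_dem.elevation
        # parcel interiors: cropland cells whose 8-neighbourhood is cropland
        interior = np.zeros_like(lc, dtype=bool)
        interior[1:-1, 1:-1] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                interior[1:-1, 1:-1] &= lc[1 + dr:lc.shape[0] - 1 + dr,
                                           1 + dc:lc.shape[1] - 1 + dc] == 1
        gy, gx = np.gradient(eta, dom.cell_size)
        slope = np.hypot(gx, gy)
        flat = interior & (slope < 0.005)
        # riser columns separate distinct flat elevations
        levels = np.unique(np.round(eta[flat], 3))
        assert flat.sum() > 10
        assert len(levels) >= 2, "need >= 2 terraced parcels"
        # interior parcel slopes below 0.5 % (cells touching a riser
        # jump on either side are the risers themselves, not parcel floor)
        jump = np.abs(np.diff(eta, axis=1, prepend=eta[:, :1])) > 0.05
        inner = interior & ~jump & ~np.roll(jump, -1, axis=1)
        assert inner.sum() > 10
        assert np.all(slope[inner] < 0.005)

    def test_invalid_domain_rejected(self):
        with pytest.raises(DomainError):
            GridDomain(2, 8)
        with pytest.raises(ParameterError):
            generate_dem(GridDomain(8, 8), "natural", relief=-1.0, seed=0)


class TestWeather:
    def test_all_dry_probabilities_give_zero_series(self):
        p = ansai_weather_params(seed=0)
        params = WeatherParams(np.zeros(12), p.gamma_shape, p.gamma_scale, 0.0, 0)
        w = generate_weather(params, 2)
        assert (w["precip_mm"] == 0).all()

    def test_seeded_determinism(self):
        p = ansai_weather_params(seed=11)
        a = generate_weather(p, 3)
        b = generate_weather(p, 3)
        assert np.array_equal(a["precip_mm"], b["precip_mm"])

    def test_monthly_means_match_closed_form(self):
        """Per-month sample means sit inside Monte-Carlo bands of the
        closed-form mean: wet_prob * shape * scale per day."""
        p = ansai_weather_params(seed=21)
        w = generate_weather(p, 28)  # ~10,000 days
        t = ansai_climate_table()
        w["month"] = pd.DatetimeIndex(w["date"]).month
        for _, row in t.iterrows():
            m = int(row["month"])
            daily = w.loc[w["month"] == m, "precip_mm"].to_numpy()
            expected = row["wet_prob"] * row["gamma_shape"] * row["gamma_scale"]
            # var of a Bernoulli-gamma mixture
            ex2 = row["wet_prob"] * row["gamma_shape"] * (row["gamma_shape"] + 1) \
                * row["gamma_scale"] ** 2
            se = np.sqrt(max(ex2 - expected**2, 1e-12) / len(daily))
            assert abs(daily.mean() - expected) < 5 * se + 0.02 * expected

    def test_annual_mean_matches_calibration(self):
        w = generate_weather(ansai_weather_params(seed=1), 40)
        annual = w.set_index("date").resample("YE")["precip_mm"].sum()
        assert abs(annual.mean() - ANSAI_MEAN_ANNUAL_MM) / ANSAI_MEAN_ANNUAL_MM < 0.05

    def test_law_of_large_numbers_200yr(self):
        w = generate_weather(ansai_weather_params(seed=2), 200)
        annual = w.set_index("date").resample("YE")["precip_mm"].sum()
        assert abs(annual.mean() - ANSAI_MEAN_ANNUAL_MM) / ANSAI_MEAN_ANNUAL_MM < 0.02

    def test_summer_maximum(self):
        w = generate_weather(ansai_weather_params(seed=3), 30)
        w["month"] = pd.DatetimeIndex(w["date"]).month
        monthly = w.groupby("month")["precip_mm"].sum()
        assert monthly.idxmax() in (7, 8, 9)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            WeatherParams(np.full(12, 1.5), np.ones(12), np.ones(12))
        with pytest.raises(ParameterError):
            WeatherParams(np.full(12, 0.3), -np.ones(12), np.ones(12))


class TestNdvi:
    dates = pd.date_range("2001-01-01", "2001-12-31", freq="D")

    def test_winter_dormancy(self):
        ndvi = generate_ndvi("natural", self.dates)
        assert (ndvi[self.dates.month == 1] <= 0.2).all()

    def test_cornfield_peak_exceeds_natural(self):
        nat = generate_ndvi("natural", self.dates)
        corn = generate_ndvi("cornfield", self.dates)
        july = self.dates.month == 7
        assert corn[july].max() > nat[july].max()
        assert corn.max() > nat.max()

    def test_bounds_and_growing_season_peak(self):
        for kind in ("natural", "cornfield"):
            ndvi = generate_ndvi(kind, self.dates)
            assert ((ndvi >= 0) & (ndvi <= 1)).all()
            peak_month = self.dates[np.argmax(ndvi.to_numpy())].month
            assert 5 <= peak_month <= 9

    def test_annual_periodicity(self):
        two = pd.date_range("2001-01-01", "2002-12-31", freq="D")
        ndvi = generate_ndvi("natural", two).to_numpy()
        assert np.allclose(ndvi[:365], ndvi[365:730])

    def test_empty_dates_rejected(self):
        with pytest.raises(ParameterError):
            generate_ndvi("natural", pd.DatetimeIndex([]))


class TestNdviToLitter:
    def test_zero_ndvi_gives_baseline(self):
        c = NdviLitterCurve(baseline=1e-5, beta=4.0)
        assert ndvi_to_litter(0.0, c) == pytest.approx(1e-5)

    def test_strictly_increasing_over_full_grid(self):
        grid = np.arange(0, 1.0001, 0.01)
        rates = ndvi_to_litter(grid, CORNFIELD_LITTER_CURVE)
        assert np.all(np.diff(rates) > 0)
        assert np.all(rates >= CORNFIELD_LITTER_CURVE.baseline)

    def test_doubling_scenario_is_pointwise_factor_two(self):
        grid = np.linspace(0, 1, 50)
        base = ndvi_to_litter(grid, CORNFIELD_LITTER_CURVE)
        doubled = NdviLitterCurve(2 * CORNFIELD_LITTER_CURVE.baseline,
                                  CORNFIELD_LITTER_CURVE.beta)
        assert np.allclose(ndvi_to_litter(grid, doubled), 2 * base)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            ndvi_to_litter(1.2, CORNFIELD_LITTER_CURVE)
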