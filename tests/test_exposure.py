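import numpy as np
import pandas as pd
import pytest
import xarray as xr

from heatecon.errors import ConfigError, CoverageError
from heatecon.exposure import (
    HOTHAPS_PARAMS,
    M_REST,
    METABOLIC_RATES,
    ProductivityShock,
    annualize_shock,
    daily_shift_workability,
    population_regional_mean,
    uniform_quarterly_weights,
    wbgt_lim,
    workability,
    working_days_per_quarter,
)
from heatecon.heatwaves import HeatwaveCatalogue, HeatwaveEvent
from heatecon.synthetic import grid_regions


class TestLimits:
    def test_iso_limit_values(self):
        assert np.isclose(wbgt_lim(400, "ISO"), 34.9 - 400 / 46)
        assert np.isclose(wbgt_lim(400, "ISO"), 26.2043, atol=1e-4)
        assert np.isclose(wbgt_lim(M_REST, "ISO"), 32.3565, atol=1e-4)

    def test_niosh_limit_value(self):
        assert np.isclose(wbgt_lim(200, "NIOSH"), 56.7 - 11.5 * np.log10(200))
        assert np.isclose(wbgt_lim(200, "NIOSH"), 30.2381, atol=1e-4)

    def test_nonpositive_metabolic_rate_rejected(self):
        with pytest.raises(ConfigError):
            wbgt_lim(0, "ISO")


class TestWorkability:
    @pytest.mark.parametrize("standard", ["ISO", "NIOSH"])
    @pytest.mark.parametrize("workload", ["low", "moderate", "high"])
    def test_ramp_endpoints(self, standard, workload):
        m = METABOLIC_RATES[workload]
        assert workability(wbgt_lim(m, standard), workload, standard) == 1.0
        assert workability(wbgt_lim(M_REST, standard), workload, standard) == 0.0

    def test_iso_moderate_interior_value(self):
        lim_rest, lim = 34.9 - 117 / 46, 34.9 - 300 / 46
        expected = (lim_rest - 30.0) / (lim_rest - lim)
        assert np.isclose(workability(30.0, "moderate", "ISO"), expected)
        assert np.isclose(expected, 0.5924, atol=1e-4)

    def test_hothaps_midpoint_and_floor(self):
        a1, _ = HOTHAPS_PARAMS["low"]
        assert np.isclose(workability(a1, "low", "Hothaps"), 0.55)
        for workload in HOTHAPS_PARAMS:
            assert np.isclose(workability(80.0, workload, "Hothaps"), 0.1, atol=5e-5)

    @pytest.mark.parametrize("standard", ["ISO", "NIOSH", "Hothaps"])
    def test_monotone_nonincreasing_in_wbgt(self, standard):
        grid = np.linspace(0.0, 60.0, 400)
        for workload in ("low", "moderate", "high"):
            vals = workability(grid, workload, standard)
            assert np.all(np.diff(vals) <= 1e-12)

    def test_bounds_and_attainment(self):
        grid = np.linspace(-10.0, 90.0, 300)
        for standard in ("ISO", "NIOSH"):
            vals = workability(grid, "high", standard)
            assert vals.min() == 0.0 and vals.max() == 1.0
        vals = workability(grid, "high", "Hothaps")
        assert np.isclose(vals.min(), 0.1, atol=1e-6) and np.isclose(vals.max(), 1.0)

    def test_heavier_workload_loses_more(self):
        grid = np.linspace(26.0, 40.0, 50)
        for standard in ("ISO", "NIOSH", "Hothaps"):
            lo = workability(grid, "low", standard)
            hi = workability(grid, "high", standard)
            assert np.all(hi <= lo + 1e-12)

    def test_sensitivity_ordering_iso_niosh_hothaps(self):
        """Damage ordering ISO ≥ NIOSH ≥ Hothaps in a moderate heat regime."""
        grid = np.linspace(27.0, 33.0, 100)
        for workload in ("moderate", "high"):
            damages = {
                s: np.mean(1.0 - workability(grid, workload, s)) for s in ("ISO", "NIOSH", "Hothaps")
            }
            assert damages["ISO"] >= damages["NIOSH"] >= damages["Hothaps"]

    def test_unknown_standard_rejected(self):
        with pytest.raises(ConfigError):
            workability(30.0, "low", "OSHA")


class TestDailyShift:
    def _hourly(self, values_by_hour):
        idx = pd.date_range("2001-07-01", periods=24, freq="h")
        return pd.Series([values_by_hour(h.hour) for h in idx], index=idx)

    def test_all_ones(self):
        assert daily_shift_workability(self._hourly(lambda h: 1.0)).iloc[0] == 1.0

    def test_alternating_mean(self):
        s = self._hourly(lambda h: 1.0 if h % 2 else 0.5)
        assert daily_shift_workability(s).iloc[0] == 0.75

    def test_444_profile_iso_moderate_cross_check(self):
        from heatecon.exposure import workability as wa
        from heatecon.heat_stress import approx_hourly_444

        prof = approx_hourly_444(20.0, 30.0)
        idx = pd.date_range("2001-07-01", periods=24, freq="h")
        hourly = pd.Series(wa(prof, "moderate", "ISO"), index=idx)
        by_hand = np.mean([wa(prof[h], "moderate", "ISO") for h in range(9, 17)])
        assert np.isclose(daily_shift_workability(hourly).iloc[0], by_hand)

    def test_missing_hours_rejected(self):
        idx = pd.date_range("2001-07-01", periods=12, freq="h")  # ends at 11h
        with pytest.raises(CoverageError):
            daily_shift_workability(pd.Series(1.0, index=idx))


class TestPopulationWeighting:
    def _field(self, values):
        return xr.DataArray(
            np.asarray(values, dtype=float)[None, :, :],
            dims=("time", "lat", "lon"),
            coords={"time": [pd.Timestamp("2001-07-01")], "lat": [40.0, 40.5], "lon": [0.0, 0.5]},
        )

    def _pop(self, values):
        return xr.DataArray(
            np.asarray(values, dtype=float),
            dims=("lat", "lon"),
            coords={"lat": [40.0, 40.5], "lon": [0.0, 0.5]},
        )

    def test_uniform_field_any_population(self):
        regions = grid_regions((2, 2), 1)
        out = population_regional_mean(self._field([[7, 7], [7, 7]]), self._pop([[1, 9], [2, 5]]), regions)
        assert np.isclose(out.iloc[0, 0], 7.0)

    def test_point_population(self):
        regions = grid_regions((2, 2), 1)
        out = population_regional_mean(
            self._field([[1, 2], [3, 4]]), self._pop([[0, 0], [0, 5]]), regions
        )
        assert np.isclose(out.iloc[0, 0], 4.0)

    def test_weighted_mean_by_hand(self):
        regions = grid_regions((2, 2), 1)
        out = population_regional_mean(
            self._field([[10, 20], [10, 20]]), self._pop([[1, 3], [0, 0]]), regions
        )
        # values {10,20} with populations {1,3} → 17.5
        assert np.isclose(out.iloc[0, 0], 17.5)

    def test_zero_population_falls_back_to_unweighted(self):
        regions = grid_regions((2, 2), 1)
        with pytest.warns(UserWarning):
            out = population_regional_mean(
                self._field([[1, 2], [3, 4]]), self._pop([[0, 0], [0, 0]]), regions
            )
        assert np.isclose(out.iloc[0, 0], 2.5)


class TestAnnualShock:
    def _losses(self, year, value, columns=(("R", "s"),)):
        idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        frame = pd.DataFrame({c: value for c in columns}, index=idx)
        frame.columns = pd.MultiIndex.from_tuples(columns, names=["region", "sector"])
        return frame

    def test_no_heatwave_days_gives_zero(self):
        cat = HeatwaveCatalogue()
        w = uniform_quarterly_weights(["R"], ["s"])
        shock = annualize_shock(self._losses(2001, 0.5), cat, w, 2001)
        assert shock.tau.loc["R", "s"] == 0.0

    def test_full_year_heatwave_uniform_weights(self):
        cat = HeatwaveCatalogue([HeatwaveEvent("R", pd.Timestamp("2001-01-01"), 365, False)])
        w = uniform_quarterly_weights(["R"], ["s"])
        shock = annualize_shock(self._losses(2001, 0.5), cat, w, 2001)
        assert np.isclose(shock.tau.loc["R", "s"], 0.5)

    def test_linear_in_quarterly_weights(self):
        """Heat concentrated in Q3: τ ratio equals the Q3 weight ratio."""
        cat = HeatwaveCatalogue([HeatwaveEvent("R", pd.Timestamp("2001-07-15"), 10, True)])
        losses = self._losses(2001, 0.4, columns=(("R", "a"), ("R", "b")))
        w = uniform_quarterly_weights(["R"], ["a", "b"])
        w.loc[("R", "a")] = [0.5 / 3, 0.5 / 3, 0.5, 0.5 / 3]
        w.loc[("R", "b")] = [0.3, 0.3, 0.1, 0.3]
        shock = annualize_shock(losses, cat, w, 2001)
        assert np.isclose(shock.tau.loc["R", "a"] / shock.tau.loc["R", "b"], 5.0)

    def test_weights_must_sum_to_one(self):
        w = uniform_quarterly_weights(["R"], ["s"]) * 2.0
        with pytest.raises(ConfigError):
            annualize_shock(self._losses(2001, 0.1), HeatwaveCatalogue(), w, 2001)

    def test_tau_range_enforced(self):
        with pytest.raises(ConfigError):
            ProductivityShock(tau=pd.DataFrame({"s": [1.2]}, index=["R"]), year=2001)

    def test_working_days_sum_to_weekdays(self):
        wd = working_days_per_quarter(2001)
        assert wd.sum() == 261  # weekdays in 2001
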