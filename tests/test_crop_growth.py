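"""Crop engine: phenology, canopy, growth, water balance, season runs."""

import math
from dataclasses import replace
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ghtomato.crop_growth import (
    PRESET_BY_CASE, PRESETS, CropParams, SoilConfig, daily_biomass_delta,
    daily_hui_increment, decode_dlap, encode_dlap, fit_dlap_from_lai,
    hargreaves_pet, intercepted_par, lai_curve_for, params_from_dict,
    params_to_dict, potential_lai, simulate_season, solve_lai_curve,
    temperature_stress)
from ghtomato.gh_climate import GreenhouseWeatherDay


@pytest.mark.parametrize("code,expected", [
    (15.05, (0.15, 0.05)),
    (45.41, (0.45, 0.41)),
    (45.29, (0.45, 0.29)),
    (45.38, (0.45, 0.38)),
])
def test_decode_dlap_two_digit_convention(code, expected):
    s, f = decode_dlap(code)
    assert (s, f) == pytest.approx(expected, abs=1e-12)
    assert encode_dlap(s, f) == pytest.approx(code)


@pytest.mark.parametrize("bad", [15.0, 0.05, 100.05])
def test_decode_dlap_rejects_degenerate_codes(bad):
    with pytest.raises(ValueError):
        decode_dlap(bad)


class TestLaiCurve:
    p1, p2 = (0.15, 0.05), (0.45, 0.38)

    def test_interpolates_both_points(self):
        c = solve_lai_curve(self.p1, self.p2)
        assert abs(c(0.15) - 0.05) < 1e-9
        assert abs(c(0.45) - 0.38) < 1e-9

    def test_monotone_increasing_on_season(self):
        c = solve_lai_curve(self.p1, self.p2)
        grid = c(np.linspace(0, 1, 1001))
        assert (np.diff(grid) > 0).all()

    def test_point_order_is_irrelevant(self):
        a = solve_lai_curve(self.p1, self.p2)
        b = solve_lai_curve(self.p2, self.p1)
        assert (a.l1, a.l2) == pytest.approx((b.l1, b.l2))

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            solve_lai_curve(self.p1, self.p1)


def test_hui_increment_arithmetic():
    assert daily_hui_increment(35, 25, tg=10, phu=2000) == pytest.approx(0.01)
    assert daily_hui_increment(12, 8, tg=10, phu=2000) == 0.0  # tavg == tg
    assert daily_hui_increment(8, 4, tg=10, phu=2000) == 0.0  # never negative


class TestPotentialLai:
    def test_zero_at_season_start(self):
        c = lai_curve_for(PRESETS["HR17-con"])
        assert potential_lai(0.0, c, dmla=7) == 0.0

    def test_hits_dlap2_fraction_mid_season(self):
        # HR17 control: 38% of maximum LAI at 45% of the season
        p = PRESETS["HR17-con"]
        lai = potential_lai(0.45, lai_curve_for(p), p.dmla)
        assert lai == pytest.approx(0.38 * p.dmla, rel=1e-9)

    def test_late_season_decline_factor(self):
        c = solve_lai_curve((0.15, 0.05), (0.45, 0.38))
        at_start = potential_lai(0.9, c, dmla=7, rlad=0.1, decline_start=0.9)
        late = potential_lai(0.95, c, dmla=7, rlad=0.1, decline_start=0.9)
        assert late / at_start == pytest.approx(0.5 ** 0.1, rel=1e-9)  # ~0.9330

    def test_zero_once_heat_units_exhausted(self):
        c = solve_lai_curve((0.15, 0.05), (0.45, 0.38))
        assert potential_lai(1.0, c, dmla=7) == 0.0
        assert potential_lai(1.2, c, dmla=7) == 0.0


@pytest.mark.parametrize("tavg,expected", [
    (28.0, 1.0),            # optimum
    (10.0, 0.0),            # base
    (19.0, math.sin(math.pi / 4)),  # halfway: ~0.7071
    (46.0, 0.0),            # symmetric upper zero
    (5.0, 0.0),
])
def test_temperature_stress_shape(tavg, expected):
    assert temperature_stress(tavg, tb=28, tg=10) == pytest.approx(expected, abs=1e-12)


def test_intercepted_par_beer_law():
    assert intercepted_par(20.0, 0.0) == 0.0
    assert intercepted_par(20.0, 3.0) == pytest.approx(
        0.5 * 20 * (1 - math.exp(-0.65 * 3)), rel=1e-12)  # ~8.577
    assert intercepted_par(20.0, 60.0) == pytest.approx(10.0, rel=1e-6)  # asymptote


def test_daily_biomass_delta_scaling():
    assert daily_biomass_delta(45, 8, reg=1.0, hui=0.5) == pytest.approx(0.36)
    assert daily_biomass_delta(45, 8, reg=0.0, hui=0.5) == 0.0
    half = daily_biomass_delta(45, 8, reg=0.5, hui=0.5)
    assert half == pytest.approx(0.18)


def test_hargreaves_pet_values():
    assert hargreaves_pet(-17.8, -17.8, 20.0) == 0.0
    assert hargreaves_pet(35, 25, 20.0) == pytest.approx(0.0135 * 47.8 * 20 / 2.45)
    assert hargreaves_pet(35, 25, 0.0) == 0.0


def _flat_weather(n, tmax, tmin, sr=12.0, rh=0.7, regime="control",
                  start=date(2022, 5, 18)):
    return [GreenhouseWeatherDay(start + timedelta(days=i), tmax=tmax,
                                 tmin=tmin, rh=rh, regime=regime, sr=sr)
            for i in range(n)]


class TestSimulateSeason:
    def test_no_development_at_base_temperature(self):
        p = PRESETS["HR17-con"]
        res = simulate_season(p, _flat_weather(60, tmax=12, tmin=8))  # tavg == tg
        assert res.fruit_yield == 0.0 and res.max_lai == 0.0

    def test_yield_is_harvest_index_times_biomass(self, mean_greenhouse_series):
        for preset in PRESETS.values():
            res = simulate_season(preset, mean_greenhouse_series("control"),
                                  harvest_day=77)
            assert res.fruit_yield == preset.hi * res.biomass
            assert res.fruit_yield <= res.biomass

    def test_bit_for_bit_reproducible(self, mean_greenhouse_series):
        wx = mean_greenhouse_series("control")
        p = PRESETS["HR17-con"]
        a = simulate_season(p, wx, harvest_day=77)
        b = simulate_season(p, wx, harvest_day=77)
        assert a.fruit_yield == b.fruit_yield and a.irrigation == b.irrigation

    def test_control_case_yield_in_observed_magnitude(self, mean_greenhouse_series):
        res = simulate_season(PRESETS["HR17-con"],
                              mean_greenhouse_series("control"), harvest_day=77)
        assert 1.0 < res.fruit_yield < 10.0  # single-digit Mg/ha scale

    def test_yield_monotone_in_wa_and_dmla(self, mean_greenhouse_series):
        wx = mean_greenhouse_series("control")
        p = PRESETS["HR17-con"]
        base = simulate_season(p, wx, harvest_day=77).fruit_yield
        assert simulate_season(replace(p, wa=2 * p.wa), wx,
                               harvest_day=77).fruit_yield > base
        assert simulate_season(replace(p, dmla=p.dmla + 2), wx,
                               harvest_day=77).fruit_yield > base

    def test_state_monotonicity_and_lai_bound(self, mean_greenhouse_series):
        p = PRESETS["HR24-cont"]
        res = simulate_season(p, mean_greenhouse_series("control"),
                              return_daily=True)
        d = res.daily
        assert (np.diff(d.hui) >= 0).all()
        assert (np.diff(d.biomass) >= -1e-15).all()
        assert (d.lai <= p.dmla + 1e-12).all()

    def test_unlimited_irrigation_means_no_water_stress(self, mean_greenhouse_series):
        res = simulate_season(PRESETS["HR17-con"],
                              mean_greenhouse_series("control"),
                              return_daily=True)
        assert (res.daily.ws == 1.0).all()
        assert res.irrigation == pytest.approx(res.aet, abs=1e-9)

    def test_capped_irrigation_binds_and_costs_yield(self, mean_greenhouse_series):
        wx = mean_greenhouse_series("control")
        p = PRESETS["HR17-con"]
        soil = SoilConfig(capacity_mm=30.0)  # small store so the cap bites
        free = simulate_season(p, wx, harvest_day=77, soil=soil)
        tight = simulate_season(p, wx, harvest_day=77, soil=soil,
                                irrigation_cap_mm=20.0, return_daily=True)
        assert tight.irrigation <= 20.0 + 1e-9
        assert (tight.daily.ws < 1.0).any()
        assert tight.fruit_yield < free.fruit_yield

    def test_heat_season_yields_less_than_control_with_same_params(
            self, mean_greenhouse_series):
        """Direction of the heat effect at fixed (control) parameters over
        the full season: the hotter house exhausts its heat units early and
        loses canopy and radiation-use efficiency."""
        for preset in ("HR17-con", "HR24-cont"):
            p = PRESETS[preset]
            y_control = simulate_season(p, mean_greenhouse_series("control")).fruit_yield
            y_heat = simulate_season(p, mean_greenhouse_series("heat")).fruit_yield
            assert y_heat < y_control

    def test_yield_nonincreasing_under_beyond_optimum_warming(
            self, mean_greenhouse_series):
        p = PRESETS["HR17-con"]
        yields = []
        for dt in (0.0, 2.0, 4.0, 6.0):
            wx = [replace(d, tmax=d.tmax + dt, tmin=d.tmin + dt)
                  for d in mean_greenhouse_series("control")]
            yields.append(simulate_season(p, wx).fruit_yield)
        assert all(a >= b for a, b in zip(yields, yields[1:]))

    def test_weather_gap_detected(self):
        wx = _flat_weather(30, tmax=30, tmin=20)
        with pytest.raises(ValueError, match="gap"):
            simulate_season(PRESETS["HR17-con"], wx[:10] + wx[12:])

    def test_empty_weather_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_season(PRESETS["HR17-con"], [])


class TestFitDlap:
    def test_round_trip_from_known_curve(self):
        c = solve_lai_curve((0.15, 0.05), (0.45, 0.38))
        hui = np.linspace(0.0, 0.9, 200)
        lai = 7 * c(hui)
        assert fit_dlap_from_lai(hui, lai, dmla=7) == (15.05, 45.38)

    def test_noisy_series_recovers_codes_closely(self):
        c = solve_lai_curve((0.15, 0.05), (0.45, 0.38))
        hui = np.linspace(0.0, 0.9, 400)
        rng = np.random.default_rng(0)
        lai = 7 * c(hui) + rng.normal(0, 0.01, hui.size)
        d1, d2 = fit_dlap_from_lai(hui, lai, dmla=7)
        assert abs(d1 - 15.05) <= 0.02 and abs(d2 - 45.38) <= 0.02

    def test_degenerate_and_uncovering_series_rejected(self):
        with pytest.raises(ValueError):
            fit_dlap_from_lai([0, 0.5, 0.9], [0.0, 0.0, 0.0], dmla=7)
        with pytest.raises(ValueError, match="cover"):
            fit_dlap_from_lai([0.2, 0.4], [1.0, 2.0], dmla=7)


def test_presets_cover_all_cases_and_validate():
    assert set(PRESET_BY_CASE.values()) == set(PRESETS)
    for p in PRESETS.values():
        assert p.tb > p.tg and 0 < p.hi <= 1 and p.density == 4.7
        s1, _ = decode_dlap(p.dlap1)
        s2, _ = decode_dlap(p.dlap2)
        assert s1 < s2


def test_params_dict_round_trip():
    p = PRESETS["HR24-heat"]
    assert params_from_dict(params_to_dict(p)) == p


@given(st.integers(1, 99), st.integers(1, 99))
def test_dlap_encode_decode_inverse(whole, frac):
    code = encode_dlap(whole / 100, frac / 100)
    assert decode_dlap(code) == (whole / 100, frac / 100)


def test_invalid_params_rejected():
    good = params_to_dict(PRESETS["HR17-con"])
    for field_name, bad in (("HI", 0.0), ("TB", 5.0), ("PHU", -1.0)):
        with pytest.raises(ValueError):
            params_from_dict({**good, field_name: bad})
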