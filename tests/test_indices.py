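"""Tests for the annual agroclimatic index engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vinetrend import (
    ConfigurationError,
    GeneratorConfig,
    IndexConfig,
    InputError,
    cold_day_frequency,
    compute_annual_indices,
    daily_mean_temperature,
    frost_free_days,
    generate_daily_climate,
    growing_degree_days,
    windowed_precip_total,
    windowed_temp_mean,
)
from conftest import make_constant_grid


# -- independent brute-force day loops (oracles) ------------------------------

def brute_gdd_simple(dates, tmin, tmax, base=10.0):
    total = 0.0
    for d, lo, hi in zip(dates, tmin, tmax):
        if (d.month, d.day) >= (4, 1) and (d.month, d.day) <= (10, 31):
            tmean = (lo + hi) / 2.0
            if tmean > base:
                total += tmean - base
    return total


def brute_ffd(dates, tmin, threshold=0.0):
    last_spring, first_fall = 0, 366
    for d, lo in zip(dates, tmin):
        if lo <= threshold:
            if d.month <= 6:
                last_spring = max(last_spring, d.dayofyear)
            elif first_fall == 366:
                first_fall = min(first_fall, d.dayofyear)
    return first_fall - last_spring


def brute_fcd(dates, tmin, year, threshold=-20.0):
    count = 0
    for d, lo in zip(dates, tmin):
        in_window = (d.year == year - 1 and d.month >= 11) or (
            d.year == year and d.month <= 3
        )
        if in_window and lo < threshold:
            count += 1
    return count


def brute_precip_sum(dates, precip, start_md, end_md):
    return sum(
        p for d, p in zip(dates, precip) if start_md <= (d.month, d.day) <= end_md
    )


def brute_temp_mean(dates, tmin, tmax, start_md, end_md):
    vals = [
        (lo + hi) / 2.0
        for d, lo, hi in zip(dates, tmin, tmax)
        if start_md <= (d.month, d.day) <= end_md
    ]
    return sum(vals) / len(vals)


# -- daily mean ----------------------------------------------------------------

@pytest.mark.parametrize("tmin, tmax, expected", [(10, 20, 15), (-5, -5, -5), (0, 7, 3.5)])
def test_daily_mean_temperature(tmin, tmax, expected):
    assert daily_mean_temperature(tmin, tmax) == expected


def test_daily_mean_rejects_inverted():
    with pytest.raises(InputError):
        daily_mean_temperature(5.0, 4.0)


# -- exact arithmetic on constant grids -----------------------------------------

def test_gdd_constant_tmean_15_is_1070():
    """Tmean 15 °C over the 214-day Apr 1 - Oct 31 window, base 10: 5 x 214."""
    grid = make_constant_grid(year=1985, tmin=10.0, tmax=20.0)
    values, valid = growing_degree_days(grid, 1985)
    assert valid.all()
    assert np.allclose(values, 5.0 * 214)


def test_gdd_below_base_is_zero():
    grid = make_constant_grid(year=1985, tmin=3.0, tmax=13.0)  # Tmean 8
    values, _ = growing_degree_days(grid, 1985)
    assert np.allclose(values, 0.0)


def test_gdd_corn_method_clamps():
    # tmin 5 clamps up to 10, tmax 35 clamps down to 30 -> (10+30)/2 - 10 = 10/day
    grid = make_constant_grid(year=1985, tmin=5.0, tmax=35.0)
    values, _ = growing_degree_days(grid, 1985, IndexConfig(gdd_method="corn"))
    assert np.allclose(values, 10.0 * 214)


def test_precip_one_mm_per_day_is_window_length():
    grid = make_constant_grid(year=1985, precip=1.0)
    values, _ = windowed_precip_total(grid, 1985, ((4, 1), (10, 31)))
    assert np.allclose(values, 214.0)
    zero = make_constant_grid(year=1985, precip=0.0)
    values, _ = windowed_precip_total(zero, 1985, ((4, 1), (10, 31)))
    assert np.allclose(values, 0.0)


def test_precip_additivity_over_abutting_windows():
    grid = make_constant_grid(year=1985, precip=2.5)
    a, _ = windowed_precip_total(grid, 1985, ((4, 1), (6, 30)))
    b, _ = windowed_precip_total(grid, 1985, ((7, 1), (10, 31)))
    total, _ = windowed_precip_total(grid, 1985, ((4, 1), (10, 31)))
    assert np.allclose(a + b, total)


def test_temp_mean_constant_and_alternating():
    grid = make_constant_grid(year=1985, tmin=14.0, tmax=14.0)
    values, _ = windowed_temp_mean(grid, 1985, ((4, 1), (10, 31)))
    assert np.allclose(values, 14.0)
    alt = make_constant_grid(year=1985, tmin=10.0, tmax=10.0)
    # alternate Tmean 10/20 over the even-length April window (30 days)
    sl = (alt.dates >= pd.Timestamp("1985-04-01")) & (alt.dates <= pd.Timestamp("1985-04-30"))
    idx = np.where(sl)[0]
    alt.tmin[idx[1::2]] = 20.0
    alt.tmax[idx[1::2]] = 20.0
    values, _ = windowed_temp_mean(alt, 1985, ((4, 1), (4, 30)))
    assert np.allclose(values, 15.0)


# -- FFD conventions ------------------------------------------------------------

def test_ffd_from_constructed_freeze_dates():
    grid = make_constant_grid(year=1985, tmin=5.0, tmax=15.0)
    # last spring freeze at DOY 120, first fall freeze at DOY 290
    grid.tmin[119] = -1.0
    grid.tmin[289] = -1.0
    values, _ = frost_free_days(grid, 1985)
    assert np.allclose(values, 170.0)


def test_ffd_no_freeze_is_366():
    grid = make_constant_grid(year=1985, tmin=5.0, tmax=15.0)
    values, _ = frost_free_days(grid, 1985)
    assert np.allclose(values, 366.0)


def test_ffd_all_freeze_floors_at_adjacent_day_difference():
    # freeze every day: last spring freeze Jun 30 (DOY 181), first fall Jul 1 (182)
    grid = make_constant_grid(year=1985, tmin=-5.0, tmax=5.0)
    values, _ = frost_free_days(grid, 1985)
    assert np.allclose(values, 1.0)


def test_ffd_boundary_freeze_is_tmin_le_threshold():
    grid = make_constant_grid(year=1985, tmin=5.0, tmax=15.0)
    grid.tmin[100] = 0.0  # exactly at the 0 °C threshold counts as freeze
    values, _ = frost_free_days(grid, 1985)
    assert np.allclose(values, 366.0 - 101)


# -- FCD conventions ------------------------------------------------------------

def test_fcd_counts_and_strict_boundary():
    grid = make_constant_grid(year=1985, n_years=2, tmin=-5.0, tmax=5.0)
    values, _ = cold_day_frequency(grid, 1986)
    assert np.allclose(values, 0.0)  # -5 is not < -20
    # exactly -20.0 does not count (strict inequality); -25 does
    grid.tmin[370:375] = -25.0  # early January 1986: 5 days
    grid.tmin[380] = -20.0
    values, _ = cold_day_frequency(grid, 1986)
    assert np.allclose(values, 5.0)


def test_fcd_first_year_window_not_covered():
    grid = make_constant_grid(year=1985, tmin=-30.0, tmax=5.0)
    with pytest.raises(InputError):
        cold_day_frequency(grid, 1985)


# -- oracle equivalence on random single-pixel years ----------------------------

@pytest.fixture(scope="module")
def random_two_year_grid():
    cfg = GeneratorConfig(n_years=3, start_year=1990, n_rows=1, n_cols=1, seed=77)
    return generate_daily_climate(cfg)


def test_engine_matches_brute_force_day_loops(random_two_year_grid):
    grid = random_two_year_grid
    dates = grid.dates
    tmin = grid.tmin[:, 0, 0]
    tmax = grid.tmax[:, 0, 0]
    precip = grid.precip[:, 0, 0]
    year = 1991
    in_year = dates.year == year
    d_y, lo_y, hi_y, p_y = dates[in_year], tmin[in_year], tmax[in_year], precip[in_year]

    gdd, _ = growing_degree_days(grid, year)
    assert gdd[0, 0] == pytest.approx(brute_gdd_simple(d_y, lo_y, hi_y), abs=1e-9)

    ffd, _ = frost_free_days(grid, year)
    assert ffd[0, 0] == brute_ffd(d_y, lo_y)

    fcd, _ = cold_day_frequency(grid, year, IndexConfig(cold_threshold=-5.0))
    assert fcd[0, 0] == brute_fcd(dates, tmin, year, threshold=-5.0)

    for window in (((4, 1), (6, 30)), ((8, 1), (10, 31)), ((4, 1), (10, 31))):
        total, _ = windowed_precip_total(grid, year, window)
        assert total[0, 0] == pytest.approx(
            brute_precip_sum(d_y, p_y, *window), abs=1e-9
        )
        mean, _ = windowed_temp_mean(grid, year, window)
        assert mean[0, 0] == pytest.approx(
            brute_temp_mean(d_y, lo_y, hi_y, *window), abs=1e-9
        )


# -- monotonicity properties -----------------------------------------------------

@settings(deadline=None, derandomize=True, max_examples=15)
@given(seed=st.integers(0, 10_000))
def test_threshold_monotonicity(seed):
    grid = generate_daily_climate(
        GeneratorConfig(n_years=3, start_year=2000, n_rows=2, n_cols=2, seed=seed)
    )
    year = 2001
    gdd_10, _ = growing_degree_days(grid, year, IndexConfig(gdd_base=10.0))
    gdd_12, _ = growing_degree_days(grid, year, IndexConfig(gdd_base=12.0))
    assert np.all(gdd_12 <= gdd_10)

    ffd_0, _ = frost_free_days(grid, year, IndexConfig(freeze_threshold=0.0))
    ffd_2, _ = frost_free_days(grid, year, IndexConfig(freeze_threshold=2.0))
    assert np.all(ffd_2 <= ffd_0)

    fcd_hi, _ = cold_day_frequency(grid, year, IndexConfig(cold_threshold=-2.0))
    fcd_lo, _ = cold_day_frequency(grid, year, IndexConfig(cold_threshold=-6.0))
    assert np.all(fcd_lo <= fcd_hi)


# -- config validation ------------------------------------------------------------

def test_index_config_validation():
    with pytest.raises(ConfigurationError):
        IndexConfig(cold_threshold=5.0)  # must be below freeze threshold
    with pytest.raises(ConfigurationError):
        IndexConfig(growth_window=((6, 30), (4, 1)))
    with pytest.raises(ConfigurationError):
        IndexConfig(gdd_method="huglin")


# -- the eight-cube assembly ------------------------------------------------------

def test_compute_annual_indices_layers_and_fcd_mask():
    grid = generate_daily_climate(
        GeneratorConfig(n_years=3, start_year=2000, n_rows=2, n_cols=2, seed=8)
    )
    cubes = compute_annual_indices(grid)
    assert set(cubes) == {
        "GDD", "FCD", "FFD", "SPRING_T", "PRECIP_GROWTH", "PRECIP_ROT", "GST", "GS_PRECIP"
    }
    for cube in cubes.values():
        assert cube.shape == (3, 2, 2)
        assert np.array_equal(cube.years, [2000, 2001, 2002])
    # first year's winter window reaches before the grid: invalid
    assert not cubes["FCD"].valid[0].any()
    assert cubes["FCD"].valid[1:].all()
    # nonnegativity where valid
    for name in ("GDD", "FCD", "FFD", "PRECIP_GROWTH", "PRECIP_ROT", "GS_PRECIP"):
        v = cubes[name].values
        assert np.all(v[np.isfinite(v)] >= 0)


def test_missing_july_day_invalidates_only_july_dependent_indices():
    grid = generate_daily_climate(
        GeneratorConfig(n_years=3, start_year=2000, n_rows=2, n_cols=2, seed=9)
    )
    i = grid.dates.get_loc(pd.Timestamp("2001-07-10"))
    grid.tmin[i, 0, 0] = np.nan
    grid.tmax[i, 0, 0] = np.nan
    grid.precip[i, 0, 0] = np.nan
    cubes = compute_annual_indices(grid)
    year_idx = 1
    for name in ("GDD", "GST", "GS_PRECIP", "FFD"):
        assert not cubes[name].valid[year_idx, 0, 0]
        assert cubes[name].valid[year_idx, 1, 1]  # neighbours unaffected
    # windows not covering July stay valid
    for name in ("SPRING_T", "PRECIP_GROWTH", "PRECIP_ROT"):
        assert cubes[name].valid[year_idx, 0, 0]


def test_noise_free_trend_propagates_linearly_to_gst():
    # 1985-1987 are all non-leap years, so the seasonal term contributes
    # identically each year and the injected trend passes through exactly
    cfg = GeneratorConfig(
        n_years=3, start_year=1985, n_rows=2, n_cols=2,
        daily_noise_sd=0.0, ar1_coeff=0.0, ns_gradient=0.0, t_trend=0.05, seed=0,
    )
    cubes = compute_annual_indices(generate_daily_climate(cfg))
    gst = cubes["GST"].values
    diffs = np.diff(gst, axis=0)
    assert np.allclose(diffs, 0.05, atol=1e-9)


def test_grid_without_full_year_rejected():
    dates = pd.date_range("2001-03-01", "2001-12-31", freq="D")
    from vinetrend import ClimateGrid

    grid = ClimateGrid(
        dates=dates,
        tmin=np.zeros((len(dates), 1, 1)),
        tmax=np.ones((len(dates), 1, 1)),
        precip=np.zeros((len(dates), 1, 1)),
    )
    with pytest.raises(InputError):
        compute_annual_indices(grid)
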