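"""Annual agroclimatic indices for viticulture, computed per pixel from daily climate.

Eight variables are derived from daily tmin/tmax/precip cubes, one value per
pixel per calendar year:

==============  =====================================================  ============
name            definition                                             units
==============  =====================================================  ============
GDD             growing degree days above a base (default 10 °C)       degree-days
                over the growing season (default Apr 1 - Oct 31)
FCD             frequency of cold days: winter days (Nov 1 of the      days
                prior year - Mar 31) with tmin strictly below a
                damaging threshold (default -20 °C)
FFD             frost-free days: day-of-year of the first fall         days
                freeze minus day-of-year of the last spring freeze
                (freeze = tmin <= 0 °C)
SPRING_T        mean daily temperature, spring window                  °C
PRECIP_GROWTH   total precipitation, vine growth window                mm
PRECIP_ROT      total precipitation, fruit-rot risk window             mm
GST             mean daily temperature over the growing season         °C
GS_PRECIP       total precipitation over the growing season            mm
==============  =====================================================  ============

A pixel-year is *invalid* — NaN, never a partial sum — whenever any day the
variable's window requires is missing, because partial windows bias trend
slopes.  The winter (FCD) window is assigned to the year containing January,
so the first year of any series is invalid for FCD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .synthetic import ClimateGrid

__all__ = [
    "IndexConfig",
    "IndexCube",
    "VARIABLES",
    "daily_mean_temperature",
    "growing_degree_days",
    "frost_free_days",
    "cold_day_frequency",
    "windowed_precip_total",
    "windowed_temp_mean",
    "compute_annual_indices",
]

MonthDay = tuple[int, int]

VARIABLES = (
    "GDD", "FCD", "FFD", "SPRING_T", "PRECIP_GROWTH", "PRECIP_ROT", "GST", "GS_PRECIP",
)

UNITS = {
    "GDD": "degree-days",
    "FCD": "days",
    "FFD": "days",
    "SPRING_T": "degC",
    "PRECIP_GROWTH": "mm",
    "PRECIP_ROT": "mm",
    "GST": "degC",
    "GS_PRECIP": "mm",
}


@dataclass(frozen=True)
class IndexConfig:
    """Thresholds and date windows defining the eight annual variables.

    All windows are inclusive of both endpoints.  ``cold_window`` starts in
    the calendar year *before* the year it is assigned to (a winter belongs
    to the year containing its January).
    """

    gdd_base: float = 10.0
    gdd_method: Literal["simple", "corn"] = "simple"
    gdd_upper: float = 30.0                       # upper clamp of the corn method
    season_start: MonthDay = (4, 1)
    season_end: MonthDay = (10, 31)
    freeze_threshold: float = 0.0                 # freeze day: tmin <= threshold
    cold_threshold: float = -20.0                 # cold day: tmin < threshold (strict)
    cold_window: tuple[MonthDay, MonthDay] = ((11, 1), (3, 31))
    spring_window: tuple[MonthDay, MonthDay] = ((4, 1), (5, 31))
    growth_window: tuple[MonthDay, MonthDay] = ((4, 1), (6, 30))
    rot_window: tuple[MonthDay, MonthDay] = ((8, 1), (10, 31))

    def __post_init__(self):
        if self.gdd_method not in ("simple", "corn"):
            raise ConfigurationError(f"gdd_method must be 'simple' or 'corn', got {self.gdd_method!r}")
        if not self.cold_threshold < self.freeze_threshold:
            raise ConfigurationError(
                f"cold_threshold ({self.cold_threshold}) must be below "
                f"freeze_threshold ({self.freeze_threshold})"
            )
        for name, (start, end) in (
            ("season", (self.season_start, self.season_end)),
            ("spring_window", self.spring_window),
            ("growth_window", self.growth_window),
            ("rot_window", self.rot_window),
        ):
            if start >= end:
                raise ConfigurationError(f"{name}: start {start} must precede end {end}")
        cw_start, cw_end = self.cold_window
        # cold window crosses the year boundary: start late in the prior year
        if not (cw_start > cw_end):
            raise ConfigurationError(
                f"cold_window must cross the new year (start {cw_start} in the prior "
                f"year, end {cw_end} in the assigned year)"
            )

    def with_(self, **kwargs) -> "IndexConfig":
        return replace(self, **kwargs)


@dataclass
class IndexCube:
    """Per-pixel annual values of one variable: a year × row × col cube.

    Invalid pixel-years are NaN; ``valid`` exposes the mask.
    """

    name: str
    years: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != self.years.size:
            raise InputError("values must be (year, row, col) aligned with years")
        if self.years.size >= 2 and not np.all(np.diff(self.years) > 0):
            raise InputError("years must be strictly increasing")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def pixel_series(self, row: int, col: int) -> tuple[np.ndarray, np.ndarray]:
        """(years, values) at one pixel, including NaN layers."""
        return self.years, self.values[:, row, col]


# ---------------------------------------------------------------------------
# window helpers

def _window_bounds(year: int, window: tuple[MonthDay, MonthDay], cross_year: bool):
    (m1, d1), (m2, d2) = window
    start_year = year - 1 if cross_year else year
    return pd.Timestamp(start_year, m1, d1), pd.Timestamp(year, m2, d2)


def _window_slice(grid: ClimateGrid, start: pd.Timestamp, end: pd.Timestamp):
    """Index slice of grid.dates covering [start, end], or None if not covered."""
    if start < grid.dates[0] or end > grid.dates[-1]:
        return None
    i0 = grid.dates.searchsorted(start)
    i1 = grid.dates.searchsorted(end)
    return slice(i0, i1 + 1)


def _require_finite(valid_any: np.ndarray) -> np.ndarray:
    """Collapse per-day finiteness (days, rows, cols) to a per-pixel validity mask."""
    return np.all(valid_any, axis=0)


def _masked(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    return np.where(valid, values, np.nan)


# ---------------------------------------------------------------------------
# operations

def daily_mean_temperature(tmin, tmax):
    """(tmin + tmax) / 2; rejects tmax < tmin."""
    tmin = np.asarray(tmin, dtype=np.float64)
    tmax = np.asarray(tmax, dtype=np.float64)
    both = np.isfinite(tmin) & np.isfinite(tmax)
    if np.any(tmax[both] < tmin[both]):
        raise InputError("tmax < tmin")
    out = (tmin + tmax) / 2.0
    return out if out.ndim else float(out)


def growing_degree_days(grid: ClimateGrid, year: int, config: IndexConfig | None = None):
    """Accumulated degree-days above gdd_base over the growing season.

    ``simple``: sum of max(0, Tmean - base).  ``corn``: tmin and tmax are
    each clamped to [base, gdd_upper] before averaging and subtracting base.
    Returns (values, valid), each (rows, cols).
    """
    config = config or IndexConfig()
    start, end = _window_bounds(year, (config.season_start, config.season_end), False)
    sl = _window_slice(grid, start, end)
    if sl is None:
        raise InputError(f"GDD window {start.date()}..{end.date()} not covered by grid")
    tmin, tmax = grid.tmin[sl], grid.tmax[sl]
    valid = _require_finite(np.isfinite(tmin) & np.isfinite(tmax))
    if config.gdd_method == "simple":
        tmean = (tmin + tmax) / 2.0
        daily = np.maximum(tmean - config.gdd_base, 0.0)
    else:
        lo, hi = config.gdd_base, config.gdd_upper
        daily = (np.clip(tmin, lo, hi) + np.clip(tmax, lo, hi)) / 2.0 - lo
    with np.errstate(invalid="ignore"):
        total = np.nansum(daily, axis=0)
    return _masked(total, valid), valid


def frost_free_days(grid: ClimateGrid, year: int, config: IndexConfig | None = None):
    """Freeze-to-freeze season length in days.

    Last spring freeze is the latest day-of-year in Jan 1 - Jun 30 with
    tmin <= freeze_threshold (0 if none); first fall freeze the earliest in
    Jul 1 - Dec 31 (366 if none).  FFD is their difference, in [0, 366].
    """
    config = config or IndexConfig()
    start, end = pd.Timestamp(year, 1, 1), pd.Timestamp(year, 12, 31)
    sl = _window_slice(grid, start, end)
    if sl is None:
        raise InputError(f"calendar year {year} not covered by grid")
    tmin = grid.tmin[sl]
    dates = grid.dates[sl]
    valid = _require_finite(np.isfinite(tmin))
    doy = dates.dayofyear.to_numpy()
    spring = dates <= pd.Timestamp(year, 6, 30)
    fall = ~spring
    with np.errstate(invalid="ignore"):
        freeze = tmin <= config.freeze_threshold
    doy3 = doy[:, None, None]
    last_spring = np.max(np.where(freeze & spring[:, None, None], doy3, 0), axis=0)
    first_fall = np.min(np.where(freeze & fall[:, None, None], doy3, 367), axis=0)
    first_fall = np.where(first_fall == 367, 366, first_fall)
    ffd = (first_fall - last_spring).astype(np.float64)
    return _masked(ffd, valid), valid


def cold_day_frequency(grid: ClimateGrid, year: int, config: IndexConfig | None = None):
    """Count of winter days with tmin strictly below cold_threshold.

    The window runs from late in the prior calendar year (default Nov 1)
    through the assigned year (default Mar 31); a year whose prior-year
    portion is not covered by the grid is wholly invalid.
    """
    config = config or IndexConfig()
    start, end = _window_bounds(year, config.cold_window, cross_year=True)
    sl = _window_slice(grid, start, end)
    if sl is None:
        raise InputError(
            f"cold window {start.date()}..{end.date()} not covered by grid"
        )
    tmin = grid.tmin[sl]
    valid = _require_finite(np.isfinite(tmin))
    with np.errstate(invalid="ignore"):
        count = np.sum(tmin < config.cold_threshold, axis=0).astype(np.float64)
    return _masked(count, valid), valid


def windowed_precip_total(grid: ClimateGrid, year: int, window: tuple[MonthDay, MonthDay]):
    """Sum of daily precipitation over an inclusive within-year window, mm."""
    start, end = _window_bounds(year, window, False)
    sl = _window_slice(grid, start, end)
    if sl is None:
        raise InputError(f"precip window {start.date()}..{end.date()} not covered by grid")
    pr = grid.precip[sl]
    valid = _require_finite(np.isfinite(pr))
    total = np.nansum(pr, axis=0)
    return _masked(total, valid), valid


def windowed_temp_mean(grid: ClimateGrid, year: int, window: tuple[MonthDay, MonthDay]):
    """Mean of (tmin+tmax)/2 over an inclusive within-year window, °C."""
    start, end = _window_bounds(year, window, False)
    sl = _window_slice(grid, start, end)
    if sl is None:
        raise InputError(f"temperature window {start.date()}..{end.date()} not covered by grid")
    tmin, tmax = grid.tmin[sl], grid.tmax[sl]
    valid = _require_finite(np.isfinite(tmin) & np.isfinite(tmax))
    with np.errstate(invalid="ignore"):
        mean = np.nanmean((tmin + tmax) / 2.0, axis=0)
    return _masked(mean, valid), valid


def _full_calendar_years(grid: ClimateGrid) -> np.ndarray:
    years = grid.years
    full = [
        y for y in years
        if grid.dates[0] <= pd.Timestamp(y, 1, 1) and pd.Timestamp(y, 12, 31) <= grid.dates[-1]
    ]
    return np.asarray(full, dtype=np.int64)


def compute_annual_indices(grid: ClimateGrid, config: IndexConfig | None = None) -> dict[str, IndexCube]:
    """Compute all eight IndexCubes on the grid's full calendar years.

    Years whose required window reaches outside the grid (the FCD window of
    the first year) come back as all-NaN layers rather than truncated sums.
    """
    config = config or IndexConfig()
    years = _full_calendar_years(grid)
    if years.size == 0:
        raise InputError("grid does not cover a single full calendar year")
    nr, nc = grid.n_rows, grid.n_cols
    season = (config.season_start, config.season_end)

    plans = {
        "GDD": lambda y: growing_degree_days(grid, y, config),
        "FCD": lambda y: cold_day_frequency(grid, y, config),
        "FFD": lambda y: frost_free_days(grid, y, config),
        "SPRING_T": lambda y: windowed_temp_mean(grid, y, config.spring_window),
        "PRECIP_GROWTH": lambda y: windowed_precip_total(grid, y, config.growth_window),
        "PRECIP_ROT": lambda y: windowed_precip_total(grid, y, config.rot_window),
        "GST": lambda y: windowed_temp_mean(grid, y, season),
        "GS_PRECIP": lambda y: windowed_precip_total(grid, y, season),
    }

    cubes: dict[str, IndexCube] = {}
    for name, fn in plans.items():
        layers = np.full((years.size, nr, nc), np.nan)
        for i, y in enumerate(years):
            try:
                values, _ = fn(int(y))
            except InputError:
                continue  # window not covered (e.g. first-year FCD): all-NaN layer
            layers[i] = values
        cubes[name] = IndexCube(name=name, years=years, values=layers, units=UNITS[name])
    return cubes
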