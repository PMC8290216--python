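"""Stochastic daily weather generator for a small regular grid.

Emulates the structure of a 4-km gridded daily climate product over a
humid-continental region (Great Lakes style): a seasonal temperature cycle
peaking in mid-July, a north-south gradient across grid rows, AR(1)
day-to-day temperature anomalies, Bernoulli wet-day occurrence with
monthly probabilities, gamma-distributed wet-day amounts, and optional
linear per-year trends in both temperature and wet-day precipitation.
Trends are injected linearly in calendar year, which is exactly the shape
Sen's slope estimates — the generator exists so that index computation and
trend detection can be validated by parameter recovery.

All randomness flows from a single integer seed through spawned
`numpy.random.Generator` streams, so one seed reproduces the full grid
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError, InputError
from .trend import AnnualSeries

__all__ = ["GeneratorConfig", "ClimateGrid", "generate_daily_climate", "generate_annual_series"]

# Day-of-year of the seasonal temperature peak (mid-July, northern hemisphere).
_PEAK_DOY = 196.0
_YEAR_LENGTH = 365.25

# Michigan Lower Peninsula-like monthly wet-day probabilities (Jan..Dec).
_DEFAULT_WET_PROB = (0.30, 0.28, 0.32, 0.36, 0.38, 0.36, 0.33, 0.34, 0.38, 0.36, 0.36, 0.33)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic daily-climate generator.

    Temperature model (daily mean, °C)::

        T(t, r, c) = mean_annual_t
                     + seasonal_amplitude * cos(2*pi*(doy - 196)/365.25)
                     + ns_gradient * r
                     + t_trend * (year - start_year)
                     + AR(1) anomaly (marginal sd = daily_noise_sd)

    tmax/tmin sit diurnal_range/2 above/below the mean, with a small
    range perturbation (sd = 0.1 * daily_noise_sd) clamped so the
    range never goes negative — tmax >= tmin is structural.

    Precipitation: each day is wet with wet_prob_by_month[month];
    wet-day amounts are Gamma(precip_shape, precip_scale) mm scaled by
    (1 + p_trend * (year - start_year) / (precip_shape * precip_scale)),
    i.e. p_trend is the drift of the expected wet-day amount in mm/year.
    `t_trend` and `p_trend` may be scalars or (n_rows, n_cols) fields.
    """

    n_years: int = 37
    start_year: int = 1983
    n_rows: int = 20
    n_cols: int = 20
    mean_annual_t: float = 8.0          # °C, annual-mean daily mean temperature
    seasonal_amplitude: float = 14.0    # °C, half peak-to-trough of the annual cycle
    diurnal_range: float = 10.0         # °C, tmax - tmin
    ns_gradient: float = 0.06           # °C per grid row (row 0 = north, coolest)
    ar1_coeff: float = 0.7              # day-to-day anomaly persistence
    daily_noise_sd: float = 3.5         # °C, marginal sd of the AR(1) anomaly
    t_trend: float | np.ndarray = 0.0   # °C per year
    wet_prob_by_month: Sequence[float] = _DEFAULT_WET_PROB
    precip_shape: float = 0.8           # gamma shape of wet-day amounts
    precip_scale: float = 8.0           # gamma scale, mm
    p_trend: float | np.ndarray = 0.0   # mm per year drift of mean wet-day amount
    seed: int = 0

    def validate(self) -> None:
        if self.n_years < 3:
            raise ConfigurationError(f"n_years must be >= 3, got {self.n_years}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError(
                f"grid shape must be positive, got n_rows={self.n_rows}, n_cols={self.n_cols}"
            )
        if not 0 <= self.ar1_coeff < 1:
            raise ConfigurationError(f"ar1_coeff must lie in [0, 1), got {self.ar1_coeff}")
        if self.daily_noise_sd < 0:
            raise ConfigurationError(f"daily_noise_sd must be >= 0, got {self.daily_noise_sd}")
        if self.diurnal_range < 0:
            raise ConfigurationError(f"diurnal_range must be >= 0, got {self.diurnal_range}")
        probs = np.asarray(self.wet_prob_by_month, dtype=float)
        if probs.shape != (12,) or np.any(probs < 0) or np.any(probs > 1):
            raise ConfigurationError(
                "wet_prob_by_month must be 12 probabilities in [0, 1]"
            )
        if self.precip_shape <= 0:
            raise ConfigurationError(f"precip_shape must be > 0, got {self.precip_shape}")
        if self.precip_scale <= 0:
            raise ConfigurationError(f"precip_scale must be > 0, got {self.precip_scale}")
        for name in ("t_trend", "p_trend"):
            val = np.asarray(getattr(self, name), dtype=float)
            if val.ndim not in (0, 2):
                raise ConfigurationError(f"{name} must be a scalar or a 2-D per-pixel field")
            if val.ndim == 2 and val.shape != (self.n_rows, self.n_cols):
                raise ConfigurationError(
                    f"{name} field shape {val.shape} does not match grid "
                    f"({self.n_rows}, {self.n_cols})"
                )

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass
class ClimateGrid:
    """Daily gridded climate: tmin/tmax (°C) and precip (mm) cubes, time × row × col.

    Missing cells are NaN; ``missing_mask`` marks them.  Dates are gap-free
    daily (leap days included) and strictly increasing.
    """

    dates: pd.DatetimeIndex
    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)     # (y, x) of the grid's first cell
    spacing: tuple[float, float] = (4.0, 4.0)    # cell size, km

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(self.dates)
        for name in ("tmin", "tmax", "precip"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
        self.validate()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tmin.shape

    @property
    def n_rows(self) -> int:
        return self.shape[1]

    @property
    def n_cols(self) -> int:
        return self.shape[2]

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.dates.year.to_numpy())

    @property
    def missing_mask(self) -> np.ndarray:
        """True where any of the three variables is missing."""
        return ~(np.isfinite(self.tmin) & np.isfinite(self.tmax) & np.isfinite(self.precip))

    def validate(self) -> None:
        t = len(self.dates)
        for name in ("tmin", "tmax", "precip"):
            arr = getattr(self, name)
            if arr.ndim != 3 or arr.shape[0] != t:
                raise InputError(f"{name} must be (time, row, col) with {t} time steps")
        if self.tmin.shape != self.tmax.shape or self.tmin.shape != self.precip.shape:
            raise InputError("tmin, tmax and precip must share one shape")
        if t >= 2:
            deltas = np.diff(self.dates.to_numpy())
            if not np.all(deltas == np.timedelta64(1, "D")):
                raise InputError("dates must be strictly increasing, gap-free daily")
        both = np.isfinite(self.tmin) & np.isfinite(self.tmax)
        if np.any(self.tmax[both] < self.tmin[both]):
            raise InputError("tmax < tmin at some present cells")
        present = np.isfinite(self.precip)
        if np.any(self.precip[present] < 0):
            raise InputError("negative precipitation at some present cells")


def _per_pixel(value, n_rows: int, n_cols: int) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if arr.ndim == 0:
        return np.full((n_rows, n_cols), float(arr))
    return arr


def _ar1_noise(rng: np.random.Generator, shape, rho: float, marginal_sd: float) -> np.ndarray:
    """AR(1) anomalies along axis 0 with the given stationary (marginal) sd."""
    if marginal_sd == 0:
        return np.zeros(shape)
    innov_sd = marginal_sd * np.sqrt(1.0 - rho**2)
    innov = rng.normal(0.0, innov_sd, size=shape)
    if rho == 0:
        return innov
    x0 = rng.normal(0.0, marginal_sd, size=shape[1:])
    out, _ = lfilter([1.0], [1.0, -rho], innov, axis=0, zi=(rho * x0)[None, ...])
    return out


def generate_daily_climate(config: GeneratorConfig) -> ClimateGrid:
    """Generate a gap-free daily ClimateGrid of ``config.n_years`` full calendar years."""
    config.validate()
    nr, nc = config.n_rows, config.n_cols
    dates = pd.date_range(
        f"{config.start_year}-01-01",
        f"{config.start_year + config.n_years - 1}-12-31",
        freq="D",
    )
    nt = len(dates)
    doy = dates.dayofyear.to_numpy().astype(np.float64)
    year_index = (dates.year.to_numpy() - config.start_year).astype(np.float64)
    month = dates.month.to_numpy()

    rng = np.random.default_rng(config.seed)
    rng_temp, rng_diurnal, rng_wet, rng_amount = rng.spawn(4)

    seasonal = config.seasonal_amplitude * np.cos(2.0 * np.pi * (doy - _PEAK_DOY) / _YEAR_LENGTH)
    base = (config.mean_annual_t + seasonal)[:, None, None]
    gradient = (config.ns_gradient * np.arange(nr, dtype=np.float64))[None, :, None]
    t_trend = _per_pixel(config.t_trend, nr, nc)
    trend = year_index[:, None, None] * t_trend[None, :, :]
    noise = _ar1_noise(rng_temp, (nt, nr, nc), config.ar1_coeff, config.daily_noise_sd)

    tmean = base + gradient + trend + noise

    # Diurnal range perturbation scales with the noise level so that a
    # noise-free configuration is fully deterministic; clamped nonnegative
    # so tmax >= tmin can never be violated.
    if config.daily_noise_sd > 0:
        pert = rng_diurnal.normal(0.0, 0.1 * config.daily_noise_sd, size=(nt, nr, nc))
        dr = np.maximum(config.diurnal_range + pert, 0.0)
    else:
        dr = np.full((nt, nr, nc), config.diurnal_range)
    tmax = tmean + dr / 2.0
    tmin = tmean - dr / 2.0

    wet_p = np.asarray(config.wet_prob_by_month, dtype=np.float64)[month - 1]
    wet = rng_wet.random((nt, nr, nc)) < wet_p[:, None, None]
    amounts = rng_amount.gamma(config.precip_shape, config.precip_scale, size=(nt, nr, nc))
    mean_amount = config.precip_shape * config.precip_scale
    p_trend = _per_pixel(config.p_trend, nr, nc)
    scale = 1.0 + year_index[:, None, None] * p_trend[None, :, :] / mean_amount
    precip = np.where(wet, amounts * np.maximum(scale, 0.0), 0.0)

    return ClimateGrid(dates=dates, tmin=tmin, tmax=tmax, precip=precip)


def generate_annual_series(
    n: int, intercept: float, slope: float, noise_sd: float, seed: int
) -> np.ndarray:
    """1-D fixture: x_t = intercept + slope*t + N(0, noise_sd²), t = 0..n-1."""
    if n < 3:
        raise InputError(f"n must be >= 3, got {n}")
    if noise_sd < 0:
        raise InputError(f"noise_sd must be >= 0, got {noise_sd}")
    t = np.arange(n, dtype=np.float64)
    rng = np.random.default_rng(seed)
    return intercept + slope * t + rng.normal(0.0, noise_sd, size=n)


def annual_series(n: int, intercept: float, slope: float, noise_sd: float, seed: int,
                  start_year: int = 0) -> AnnualSeries:
    """Convenience wrapper returning an AnnualSeries ready for mk_test."""
    return AnnualSeries.from_values(
        generate_annual_series(n, intercept, slope, noise_sd, seed), start_year
    )
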