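"""Per-pixel trend analysis over analysis windows: the mapping stage.

Each agroclimatic variable's annual cube is tested pixel by pixel, for each
analysis window (an inclusive span of calendar years), with the
Mann-Kendall test and Sen's slope.  The result is a TrendRaster: slope,
tau and p layers plus significance and validity masks.  Non-significant
pixels are the map's "white pixels" — they are encoded as NaN (no-data) in
the masked slope layer, never as zero, so that no-change is
distinguishable from a zero slope.

Testing is deliberately per-pixel and independent, with no spatial
multiple-testing adjustment; changed-area proportions therefore carry the
per-pixel false-positive rate alpha under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .indices import IndexCube
from .trend import DEFAULT_ALPHA, AnnualSeries, mk_test

__all__ = [
    "AnalysisWindow",
    "TrendRaster",
    "PAPER_WINDOW_SPANS",
    "build_windows",
    "pixelwise_trend",
    "changed_area_proportion",
    "summarize",
]

# The nine default analysis windows of the 1983-2019 study design.
PAPER_WINDOW_SPANS = (
    (1983, 2019),  # entire period, 37 years
    (1983, 2002),  # first 20 years
    (2000, 2019),  # last 20 years
    (1983, 1994),  # first 12 years
    (1995, 2006),  # middle 12 years
    (2007, 2019),  # last 13 years
    (1983, 2012),  # first 30 years
    (1990, 2019),  # last 30 years
    (2012, 2019),  # last 8 years
)


@dataclass(frozen=True)
class AnalysisWindow:
    """A named inclusive span of calendar years."""

    start_year: int
    end_year: int

    def __post_init__(self):
        if self.start_year > self.end_year:
            raise ConfigurationError(
                f"window start_year {self.start_year} exceeds end_year {self.end_year}"
            )
        if self.n_years < 3:
            raise ConfigurationError(
                f"window {self.label}: n_years must be >= 3 for trend testing, "
                f"got {self.n_years}"
            )

    @property
    def label(self) -> str:
        return f"{self.start_year}–{self.end_year}"

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


def build_windows(spans=None, data_years=None) -> list[AnalysisWindow]:
    """Build the ordered analysis-window list.

    With no ``spans``, returns the nine default windows.  ``data_years``
    (an iterable of available years) triggers a coverage check: every window
    must lie inside the data's year range.
    """
    spans = PAPER_WINDOW_SPANS if spans is None else tuple(tuple(s) for s in spans)
    windows = [AnalysisWindow(int(a), int(b)) for a, b in spans]
    if data_years is not None:
        data_years = np.asarray(list(data_years), dtype=np.int64)
        lo, hi = int(data_years.min()), int(data_years.max())
        for w in windows:
            if w.start_year < lo or w.end_year > hi:
                raise ConfigurationError(
                    f"window {w.label} outside the data's year range {lo}–{hi}"
                )
    return windows


@dataclass
class TrendRaster:
    """Per-pixel Mann-Kendall / Sen's-slope results for one variable and window."""

    variable: str
    window: AnalysisWindow
    alpha: float
    sen_slope: np.ndarray    # units/yr, NaN where invalid
    tau: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray  # bool
    valid: np.ndarray        # bool
    units: str = ""

    @property
    def masked_slope(self) -> np.ndarray:
        """Slope with non-significant or invalid pixels as NaN (map no-data)."""
        return np.where(self.significant & self.valid, self.sen_slope, np.nan)


def pixelwise_trend(cube: IndexCube, window: AnalysisWindow, alpha: float = DEFAULT_ALPHA) -> TrendRaster:
    """Run the Mann-Kendall test and Sen's slope on every pixel's windowed series.

    A pixel is invalid if any year inside the window is invalid for it.
    """
    wanted = np.arange(window.start_year, window.end_year + 1)
    present = np.isin(wanted, cube.years)
    if not np.all(present):
        missing = wanted[~present]
        raise InputError(
            f"cube '{cube.name}' does not cover window {window.label}: "
            f"missing years {missing.tolist()}"
        )
    idx = np.searchsorted(cube.years, wanted)
    values = cube.values[idx]                 # (n_years, rows, cols)
    valid = np.all(np.isfinite(values), axis=0)

    nr, nc = valid.shape
    slope = np.full((nr, nc), np.nan)
    tau = np.full((nr, nc), np.nan)
    p = np.full((nr, nc), np.nan)
    sig = np.zeros((nr, nc), dtype=bool)
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            res = mk_test(AnnualSeries(wanted, values[:, r, c]), alpha=alpha)
            slope[r, c] = res.sen_slope
            tau[r, c] = res.tau
            p[r, c] = res.p_value
            sig[r, c] = res.significant
    return TrendRaster(
        variable=cube.name,
        window=window,
        alpha=alpha,
        sen_slope=slope,
        tau=tau,
        p_value=p,
        significant=sig,
        valid=valid,
        units=cube.units,
    )


def changed_area_proportion(raster: TrendRaster, split: bool = False):
    """Fraction of valid pixels whose trend is significant.

    With ``split=True`` returns a dict {"total", "increasing", "decreasing"};
    the signed parts partition the total by the sign of Sen's slope among
    significant pixels.
    """
    n_valid = int(raster.valid.sum())
    if n_valid == 0:
        raise InputError("changed-area proportion undefined: zero valid pixels")
    sig = raster.significant & raster.valid
    total = sig.sum() / n_valid
    if not split:
        return float(total)
    pos = (sig & (raster.sen_slope > 0)).sum() / n_valid
    neg = (sig & (raster.sen_slope < 0)).sum() / n_valid
    return {"total": float(total), "increasing": float(pos), "decreasing": float(neg)}


def summarize(cubes: dict[str, IndexCube], windows, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """One row per variable × window: changed-area proportions and slope stats.

    Slope statistics (min/median/max) are taken among significant pixels
    only and are NaN when nothing is significant.
    """
    rows = []
    for name, cube in cubes.items():
        for w in windows:
            raster = pixelwise_trend(cube, w, alpha=alpha)
            n_valid = int(raster.valid.sum())
            if n_valid == 0:
                rows.append({
                    "variable": name, "window": w.label, "n_years": w.n_years,
                    "n_valid": 0, "n_significant": 0,
                    "prop_changed": np.nan, "prop_increasing": np.nan,
                    "prop_decreasing": np.nan,
                    "slope_min": np.nan, "slope_median": np.nan, "slope_max": np.nan,
                    "units_per_year": cube.units,
                })
                continue
            props = changed_area_proportion(raster, split=True)
            sig_slopes = raster.sen_slope[raster.significant & raster.valid]
            rows.append({
                "variable": name,
                "window": w.label,
                "n_years": w.n_years,
                "n_valid": n_valid,
                "n_significant": int(sig_slopes.size),
                "prop_changed": props["total"],
                "prop_increasing": props["increasing"],
                "prop_decreasing": props["decreasing"],
                "slope_min": float(sig_slopes.min()) if sig_slopes.size else np.nan,
                "slope_median": float(np.median(sig_slopes)) if sig_slopes.size else np.nan,
                "slope_max": float(sig_slopes.max()) if sig_slopes.size else np.nan,
                "units_per_year": cube.units,
            })
    return pd.DataFrame(rows)
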