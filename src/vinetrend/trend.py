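"""Mann-Kendall trend test and Sen's slope estimator for annual series.

The Mann-Kendall S statistic sums the signs of all forward-looking pairwise
differences of a series::

    S = sum_{k<j} sign(x_j - x_k),   sign(d) = +1 (d>0), 0 (d=0), -1 (d<0)

Large positive S indicates a persistent increase, large negative S a
decrease.  Significance uses the normal approximation with the standard
tie-corrected variance

    var(S) = [ n(n-1)(2n+5) - sum_g t_g(t_g-1)(2t_g+5) ] / 18

(summed over tie groups g of extent t_g) and a +/-1 continuity correction
in the standardised statistic Z.  An exact null distribution of S (by
inversion-count convolution) is available for short tie-free series.

Sen's slope is the median of all pairwise slopes
(x_j - x_k)/(t_j - t_k), a robust estimate of the rate of change per year.

Everything here is written from first principles on purpose: the pairwise
kernel is the quantity under study.  scipy is used only for the normal
distribution and (in the test-suite) as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "AnnualSeries",
    "TrendResult",
    "mk_sign",
    "mk_s_statistic",
    "mk_variance",
    "kendall_tau",
    "mk_test",
    "sens_slope",
    "read_series_csv",
]

DEFAULT_ALPHA = 0.10


@dataclass(frozen=True)
class AnnualSeries:
    """An annual time series: strictly increasing integer years and finite values."""

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.ndim != 1 or years.size != values.size:
            raise InputError("years and values must be 1-D and of equal length")
        if years.size >= 2 and not np.all(np.diff(years) > 0):
            raise InputError("years must be strictly increasing with no duplicates")
        if not np.all(np.isfinite(values)):
            raise InputError("values must be finite")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @classmethod
    def from_values(cls, values: Sequence[float], start_year: int = 0) -> "AnnualSeries":
        values = np.asarray(values, dtype=np.float64)
        return cls(start_year + np.arange(values.size), values)


@dataclass(frozen=True)
class TrendResult:
    """Full outcome of a Mann-Kendall test plus Sen's slope on one series."""

    s: int
    var_s: float
    z: float
    p_value: float
    tau: float
    sen_slope: float
    alpha: float
    significant: bool
    direction: Literal["increasing", "decreasing", "none"]
    n: int
    sen_ci: tuple[float, float] | None = field(default=None)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "S": self.s,
            "var_S": self.var_s,
            "Z": self.z,
            "p_value": self.p_value,
            "tau": self.tau,
            "sen_slope": self.sen_slope,
            "alpha": self.alpha,
            "significant": self.significant,
            "direction": self.direction,
        }


def mk_sign(later: float, earlier: float) -> int:
    """Sign kernel of the S statistic for one ordered pair (earlier, later)."""
    d = later - earlier
    if d > 0:
        return 1
    if d < 0:
        return -1
    return 0


def _as_series(series) -> AnnualSeries:
    if isinstance(series, AnnualSeries):
        return series
    return AnnualSeries.from_values(np.asarray(series, dtype=np.float64))


def mk_s_statistic(series) -> int:
    """Mann-Kendall S: the sum of sign(x_j - x_k) over all pairs k < j."""
    s = _as_series(series)
    if s.n < 2:
        raise InputError(f"Mann-Kendall S requires n >= 2, got n={s.n}")
    x = s.values
    iu, ju = np.triu_indices(s.n, k=1)
    return int(np.sign(x[ju] - x[iu]).sum())


def mk_variance(series) -> float:
    """Tie-corrected variance of S under the null of no trend."""
    s = _as_series(series)
    n = s.n
    if n < 3:
        raise InputError(f"Mann-Kendall variance requires n >= 3, got n={n}")
    _, counts = np.unique(s.values, return_counts=True)
    ties = counts[counts > 1].astype(np.float64)
    correction = np.sum(ties * (ties - 1) * (2 * ties + 5))
    return (n * (n - 1) * (2 * n + 5) - correction) / 18.0


def kendall_tau(series, variant: Literal["a", "b"] = "a") -> float:
    """Kendall rank correlation of values against time.

    tau-a divides S by the total pair count n(n-1)/2; tau-b additionally
    corrects the denominator for tied values (tau-b equals tau-a when no
    values tie, since years never tie).
    """
    s = _as_series(series)
    if s.n < 2:
        raise InputError("tau requires n >= 2")
    n_pairs = s.n * (s.n - 1) / 2.0
    S = mk_s_statistic(s)
    if variant == "a":
        return S / n_pairs
    if variant == "b":
        _, counts = np.unique(s.values, return_counts=True)
        t = counts[counts > 1].astype(np.float64)
        tied = np.sum(t * (t - 1) / 2.0)
        denom = np.sqrt(n_pairs * (n_pairs - tied))
        return float("nan") if denom == 0 else S / denom
    raise InputError(f"unknown tau variant {variant!r}")


def _exact_s_pvalue(s_obs: int, n: int) -> float:
    """Two-sided exact p for S under the tie-free null, by convolution.

    The null distribution of the number of inversions of a random permutation
    is the convolution of uniforms on {0..i}; S = n(n-1)/2 - 2*inversions.
    """
    # counts[i] = number of permutations with i inversions
    counts = np.array([1.0])
    for i in range(1, n):
        kernel = np.ones(i + 1)
        counts = np.convolve(counts, kernel)
    total = counts.sum()
    max_s = n * (n - 1) // 2
    # inversions v maps to S = max_s - 2v; P(|S| >= |s_obs|)
    s_vals = max_s - 2 * np.arange(counts.size)
    p = counts[np.abs(s_vals) >= abs(s_obs)].sum() / total
    return float(min(1.0, p))


def _prewhiten(x: np.ndarray) -> np.ndarray:
    """Remove lag-1 autocorrelation: x'_t = x_t - r1 * x_{t-1}."""
    xc = x - x.mean()
    denom = np.sum(xc * xc)
    r1 = 0.0 if denom == 0 else float(np.sum(xc[1:] * xc[:-1]) / denom)
    return x[1:] - r1 * x[:-1]


def mk_test(
    series,
    alpha: float = DEFAULT_ALPHA,
    continuity: bool = True,
    method: Literal["normal", "exact"] = "normal",
    prewhiten: bool = False,
    sen_confidence: float | None = None,
) -> TrendResult:
    """Run the Mann-Kendall test and Sen's slope on one annual series.

    Parameters
    ----------
    series : AnnualSeries or 1-D array
        The annual values; a bare array is indexed by consecutive years.
    alpha : float
        Two-sided significance level (default 0.10).
    continuity : bool
        Apply the +/-1 continuity correction to S before standardising.
    method : "normal" | "exact"
        "exact" uses the exact permutation null of S (tie-free series only;
        practical for short series).  "normal" is the tie-corrected normal
        approximation.
    prewhiten : bool
        Remove lag-1 autocorrelation from the values before testing.  Off by
        default; the trend statistic is then computed on the whitened series
        while Sen's slope is still reported on the raw one.
    sen_confidence : float, optional
        If given (e.g. 0.90), also compute a confidence band for Sen's slope
        from the rank positions +/- z*sqrt(var_S)/2 of the ordered pairwise
        slopes.
    """
    s = _as_series(series)
    if s.n < 3:
        raise InputError(f"Mann-Kendall test requires n >= 3, got n={s.n}")
    if not 0 < alpha < 1:
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")

    test_series = s
    if prewhiten:
        test_series = AnnualSeries(s.years[1:], _prewhiten(s.values))

    S = mk_s_statistic(test_series)
    var_s = mk_variance(test_series)

    if var_s == 0:
        z = 0.0
        p = 1.0
    elif method == "exact":
        _, counts = np.unique(test_series.values, return_counts=True)
        if np.any(counts > 1):
            raise InputError("exact method requires a tie-free series")
        z = _standardise(S, var_s, continuity)
        p = _exact_s_pvalue(S, test_series.n)
    else:
        z = _standardise(S, var_s, continuity)
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(1.0, p)

    slope = sens_slope(s)
    ci = None
    if sen_confidence is not None:
        ci = _sen_confidence_band(s, var_s, sen_confidence)

    significant = p < alpha
    if significant and S > 0:
        direction = "increasing"
    elif significant and S < 0:
        direction = "decreasing"
    else:
        direction = "none"

    return TrendResult(
        s=S,
        var_s=float(var_s),
        z=float(z),
        p_value=float(p),
        tau=kendall_tau(test_series, "a"),
        sen_slope=float(slope),
        alpha=alpha,
        significant=bool(significant),
        direction=direction,
        n=s.n,
        sen_ci=ci,
    )


def _standardise(S: int, var_s: float, continuity: bool) -> float:
    if S == 0:
        return 0.0
    shift = (1 if continuity else 0) * (1 if S > 0 else -1)
    return (S - shift) / np.sqrt(var_s)


def _pairwise_slopes(s: AnnualSeries) -> np.ndarray:
    iu, ju = np.triu_indices(s.n, k=1)
    return (s.values[ju] - s.values[iu]) / (s.years[ju] - s.years[iu])


def sens_slope(series) -> float:
    """Median of all pairwise slopes (units per year)."""
    s = _as_series(series)
    if s.n < 2:
        raise InputError(f"Sen's slope requires n >= 2, got n={s.n}")
    return float(np.median(_pairwise_slopes(s)))


def _sen_confidence_band(s: AnnualSeries, var_s: float, confidence: float) -> tuple[float, float]:
    """Rank-based confidence interval for Sen's slope (normal approximation)."""
    slopes = np.sort(_pairwise_slopes(s))
    n_pairs = slopes.size
    if var_s <= 0 or n_pairs < 2:
        return (slopes[0], slopes[-1])
    c = stats.norm.ppf(0.5 + confidence / 2.0) * np.sqrt(var_s)
    lo = int(np.floor((n_pairs - c) / 2.0))
    hi = int(np.ceil((n_pairs + c) / 2.0))
    lo = max(lo, 0)
    hi = min(hi, n_pairs - 1)
    return (float(slopes[lo]), float(slopes[hi]))


def read_series_csv(path) -> AnnualSeries:
    """Read a two-column (year, value) CSV into an AnnualSeries."""
    from pathlib import Path

    if not Path(path).exists():
        raise InputError(f"series file not found: {path}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two columns (year, value)")
    return AnnualSeries(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
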