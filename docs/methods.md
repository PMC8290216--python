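# Methods

This note documents the models, conventions and numerical choices behind
`vinetrend`, and what the synthetic-data validation does and does not
demonstrate about real gridded climate products.

## Trend detection: Mann-Kendall and Sen's slope

The core statistic is the pairwise sign sum
S = Σ_{k<j} sign(x_j − x_k) over an annual series of length n. It is
distribution-free: any strictly increasing transform of the data leaves S
unchanged, which suits skewed climate variables (precipitation totals,
cold-day counts) where least-squares slopes are fragile.

**Variance and standardisation.** Significance uses the normal
approximation with the standard tie-corrected variance
var(S) = [n(n−1)(2n+5) − Σ_g t_g(t_g−1)(2t_g+5)]/18, where g runs over
groups of tied values of extent t_g. Z applies the ±1 continuity
correction: Z = (S−1)/√var(S) for S>0, 0 for S=0, (S+1)/√var(S) for S<0;
p is two-sided. These are the conventions of the classical literature; the
continuity correction makes the test very slightly conservative at n≈37
(empirical type-I ≈ 0.095 at α = 0.10, measured in the test suite). Both
the correction and tie handling are arguments of `mk_test`, and an exact
permutation null of S (computed by inversion-count convolution, feasible
for short tie-free series) is available as `method="exact"`.

**Degenerate series.** A constant series has var(S) = 0; the defined
result is S = 0, Z = 0, p = 1, not significant — never an exception,
because constant pixels are routine in masked rasters.

**Sen's slope** is the median of all n(n−1)/2 pairwise slopes
(x_j − x_k)/(t_j − t_k), with the midpoint convention for even pair
counts (this matches `scipy.stats.theilslopes`, which the test suite uses
as an independent cross-check). A rank-based confidence band
(`sen_confidence=`) uses the normal approximation on the ordered slope
list. Kendall's τ is reported as τ_a = S/(n(n−1)/2) by default, with τ_b
available under ties.

**What is deliberately absent.** No pre-whitening is applied by default
(a lag-1 pre-whitening option exists but annual index series at n ≤ 37
carry little autocorrelation, and pre-whitening trades false positives
for lost power); no seasonal or regional Mann-Kendall variants; no
multiple-testing adjustment across pixels — maps are thresholded at the
per-pixel α (default 0.10), so a null map is expected to show ≈ α of its
area as "changed". Changed-area proportions use valid pixels as the
denominator.

## Agroclimatic indices

All date windows are inclusive of both endpoints and evaluated on the real
(leap-aware) calendar. A pixel-year is invalid whenever any required day
is missing — partial sums are never formed, because a window that silently
shrinks in some years injects spurious trends.

- **GDD**: Σ max(0, Tmean − base) with Tmean = (tmin+tmax)/2, base 10 °C,
  April 1 – October 31 (214 days). The "corn" variant (clamp tmin and tmax
  to [base, 30 °C] before averaging) is provided because both conventions
  circulate in the viticulture literature; "simple" is the default.
- **FFD** is a *season length*, not a day count: (day-of-year of first
  fall freeze, searched July 1 – December 31, default 366 if none) minus
  (day-of-year of last spring freeze, searched January 1 – June 30,
  default 0 if none), freeze = tmin ≤ 0 °C. The typical 145–215-day range
  for the region matches this freeze-to-freeze definition. A
  freeze-every-day series degenerates to 1 (June 30 → July 1), the
  adjacent-day floor of the convention.
- **FCD**: count of days with tmin strictly below −20 °C in the
  November 1 – March 31 winter, assigned to the year containing January;
  the first year of a record is invalid rather than computed from a
  truncated winter. −20 °C sits at the widely cited vinifera damage
  boundary; like every threshold here it is configurable, and the growth
  (April–June) and rot (August–October) precipitation windows are likewise
  configurable stand-ins for phenology-specific choices that vary by
  study.
- **SPRING_T / GST**: window means of daily Tmean; **PRECIP_*\***: window
  sums of daily precipitation.

Monotonicity contracts (raising the GDD base can only lower GDD; raising
the freeze threshold can only shorten FFD; lowering the cold threshold can
only lower FCD) and window additivity of precipitation sums are
property-tested.

## Synthetic daily climate

The generator produces the *structure* the pipeline must handle, not a
re-creation of any real place:

- Daily mean temperature = annual mean (8 °C) + single cosine harmonic
  peaking at day-of-year 196 (amplitude 14 °C) + linear north–south
  gradient (0.06 °C/row) + injected linear trend (°C/yr, scalar or
  per-pixel field) + AR(1) anomalies (lag-1 coefficient 0.7, marginal sd
  3.5 °C, simulated with a stationary initial state via a linear filter).
- tmax/tmin sit ± half the diurnal range (10 °C) around the mean, with a
  small range perturbation clamped nonnegative, so tmax ≥ tmin is
  structural. The perturbation scales with the noise level so a noise-free
  configuration is exactly deterministic.
- Precipitation: Bernoulli wet days with monthly probabilities
  (≈ 0.28–0.38), wet-day amounts Gamma(shape 0.8, scale 8 mm), scaled by
  (1 + p_trend·Δyear/mean wet-day amount) — i.e. `p_trend` is the drift of
  the expected wet-day amount in mm/yr. Occurrence is independent across
  days by design: every in-scope index is a window sum, count or mean, so
  wet-spell persistence cannot affect any of them.
- One integer seed drives four spawned generator streams (temperature
  noise, diurnal perturbation, wet-day draws, amounts); identical
  seed + config is bit-identical output.

The defaults were calibrated once so that annual GDD, FFD, GST and
growing-season precipitation land inside the typical Lower-Peninsula
ranges (750–2,040 degree-days; 145–215 days; 11–19 °C; 245–1,090 mm) for
at least 95% of pixel-years, which the acceptance suite verifies on a 6×6
× 37-year run.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial correlation of weather anomalies across
pixels (pixels are independent, which is exactly what makes binomial
tolerances on changed-area proportions valid in tests, and exactly wrong
for real rasters, where spatially correlated noise widens the distribution
of map-level proportions); lake-effect and topographic structure; wet-spell
persistence; non-stationary variance; multi-harmonic seasonality. Trend
recovery results here therefore validate the *machinery*, not the power of
the method on any particular real landscape.

## Pipeline conventions

- Analysis windows are inclusive year spans; the default set is the nine
  sub-periods of a 1983–2019 study design (full 37 years; first/last 20;
  first/middle 12 and last 13; first/last 30; last 8). Windows shorter
  than 3 years are rejected.
- Per-pixel results are produced by calling the scalar `mk_test` on each
  pixel's extracted series, so raster layers are bit-identical to direct
  library calls (asserted in tests) — no vectorised shortcut that could
  drift from the reference path.
- Slope rasters carry physical units per year; τ is a separate layer.
  Non-significant pixels are NaN no-data in the masked slope layer, never
  0, so "no detected change" and "zero slope" remain distinguishable.
- NetCDF output uses xarray's scipy backend (NETCDF3_CLASSIC), keeping the
  dependency footprint to numpy/scipy/pandas/xarray; rasters are also
  writable as tidy CSV. Every `run-all` writes a provenance record
  (sha256 of the canonical config, seed, library versions).

## Problem sizes used in validation

The test and acceptance suites run at desk scale by choice: 1,000 random
series for oracle equivalence; 10,000 null series of n = 37 for the
type-I rate (±1% is ≈ 3.3 binomial standard errors); a 20×20 × 37-year
grid (≈ 5.4 M daily cells per variable) for end-to-end parameter recovery
of a 0.04 °C/yr GST trend; a 6×6 × 37-year grid for generator
calibration. These sizes keep the full suite under a minute while leaving
Monte-Carlo tolerances comfortably wider than their standard errors.

## Known limitations

- The normal approximation of S is used for all n ≥ 3; for very short
  windows (n < 10) the exact mode is more faithful but is not the default,
  matching common practice.
- Changed-area proportions on real (spatially correlated) rasters have a
  much wider null distribution than the per-pixel α suggests; the package
  reports the proportions and leaves field-significance assessment to the
  user.
- The import adapter normalises units (°C/°F/K, mm/inches/cm) and checks
  calendar integrity, but does not regrid, fill gaps, or handle
  non-Gregorian calendars.
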