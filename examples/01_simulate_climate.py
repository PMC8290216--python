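"""Simulate a small gridded daily climate record and inspect one pixel.

The generator emulates a humid-continental climate on a regular grid:
a mid-July-peaking seasonal cycle, a north-south gradient across rows,
AR(1) day-to-day temperature anomalies and gamma-distributed wet-day
precipitation.  Here we simulate 5 years on a 4x4 grid and look at the
centre pixel's July and January statistics.
"""

import numpy as np

from vinetrend import GeneratorConfig, generate_daily_climate

config = GeneratorConfig(n_years=5, start_year=2015, n_rows=4, n_cols=4, seed=42)
grid = generate_daily_climate(config)

print(f"grid: {grid.shape[0]} days x {grid.n_rows} rows x {grid.n_cols} cols "
      f"({grid.dates[0].date()} .. {grid.dates[-1].date()})")

month = grid.dates.month.to_numpy()
for name, m in (("January", 1), ("July", 7)):
    tmean = (grid.tmin[month == m, 2, 2] + grid.tmax[month == m, 2, 2]) / 2
    pr = grid.precip[month == m, 2, 2]
    print(f"{name:>7}: mean T {tmean.mean():6.1f} degC, "
          f"wet-day fraction {np.mean(pr > 0):.2f}, "
          f"mean wet-day amount {pr[pr > 0].mean():.1f} mm")

# A cold January and a warm July with year-round precipitation is the
# signature of the Great Lakes climate the generator imitates.
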