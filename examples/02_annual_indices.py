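"""Compute the eight annual agroclimatic indices from daily climate.

Each index condenses one year of daily weather at one pixel into a single
viticulture-relevant number: accumulated heat (GDD), freeze-free season
length (FFD), damaging winter cold (FCD), and seasonal temperature means
and precipitation totals.
"""

from vinetrend import GeneratorConfig, compute_annual_indices, generate_daily_climate

grid = generate_daily_climate(
    GeneratorConfig(n_years=4, start_year=2010, n_rows=3, n_cols=3, seed=7)
)
cubes = compute_annual_indices(grid)

print(f"{'year':>6}", *[f"{n:>14}" for n in cubes])
for i, year in enumerate(cubes["GDD"].years):
    row = [f"{cubes[n].values[i, 1, 1]:14.1f}" for n in cubes]
    print(f"{year:>6}", *row)

# NaN in the first FCD entry is deliberate: that year's winter window
# (November-March) starts before the record begins, and a truncated
# window would bias any later trend estimate.
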