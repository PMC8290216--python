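"""End-to-end pipeline: climate -> indices -> windows -> trends -> summary.

``run_pipeline`` is the programmatic equivalent of the ``run-all`` CLI
command.  Every run writes a machine-readable provenance record (config
hash, seed, library versions) next to its outputs, so deterministic stages
can be reproduced bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__, gridio
from .config import PipelineConfig, config_hash
from .indices import IndexCube, compute_annual_indices
from .spatial import TrendRaster, build_windows, pixelwise_trend, summarize
from .synthetic import ClimateGrid, generate_daily_climate

logger = logging.getLogger("vinetrend")

__all__ = ["PipelineResult", "run_pipeline", "write_provenance"]


@dataclass
class PipelineResult:
    grid: ClimateGrid
    cubes: dict[str, IndexCube]
    rasters: dict[tuple[str, str], TrendRaster]  # (variable, window label)
    summary: pd.DataFrame


def write_provenance(config: PipelineConfig, out_dir: Path) -> None:
    record = {
        "package": "vinetrend",
        "version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "config_hash": config_hash(config),
        "config": config.to_dict(),
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)


def run_pipeline(
    config: PipelineConfig,
    grid: ClimateGrid | None = None,
    out_dir: str | Path | None = None,
    write_rasters: bool = True,
) -> PipelineResult:
    """Run simulate/import -> indices -> per-pixel trends -> summary.

    If ``grid`` is None, a grid is imported from ``config.climate_path`` or,
    failing that, simulated from ``config.generator`` (seed overridden by
    ``config.seed``).  Outputs are written under ``out_dir`` when given.
    """
    logging.basicConfig(level=config.log_level)
    if grid is None:
        if config.climate_path:
            grid = gridio.import_external_grid(config.climate_path)
            logger.info("imported climate grid %s: shape %s", config.climate_path, grid.shape)
        else:
            grid = generate_daily_climate(config.generator.with_(seed=config.seed))
            logger.info("simulated climate grid: shape %s", grid.shape)

    cubes = compute_annual_indices(grid, config.index)
    for name, cube in cubes.items():
        logger.info(
            "index %s: %d years, %d/%d valid pixel-years",
            name, cube.years.size, int(cube.valid.sum()), cube.values.size,
        )

    windows = build_windows(config.windows, data_years=cubes["GST"].years)

    rasters: dict[tuple[str, str], TrendRaster] = {}
    for name, cube in cubes.items():
        for w in windows:
            raster = pixelwise_trend(cube, w, alpha=config.alpha)
            rasters[(name, w.label)] = raster
            logger.debug(
                "trend %s %s: %d significant of %d valid",
                name, w.label, int(raster.significant.sum()), int(raster.valid.sum()),
            )
    summary = summarize(cubes, windows, alpha=config.alpha)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gridio.write_climate_netcdf(grid, out_dir / "climate.nc")
        idx_dir = out_dir / "indices"
        idx_dir.mkdir(exist_ok=True)
        for name, cube in cubes.items():
            gridio.write_index_netcdf(cube, idx_dir / f"{name}.nc")
        if write_rasters:
            trend_dir = out_dir / "trends"
            trend_dir.mkdir(exist_ok=True)
            for (name, label), raster in rasters.items():
                span = f"{raster.window.start_year}-{raster.window.end_year}"
                gridio.write_trend_netcdf(raster, trend_dir / f"{name}_{span}.nc")
        summary.to_csv(out_dir / "summary.csv", index=False)
        write_provenance(config, out_dir)
        logger.info("wrote outputs to %s", out_dir)

    return PipelineResult(grid=grid, cubes=cubes, rasters=rasters, summary=summary)
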