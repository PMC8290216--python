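"""Pipeline configuration: one YAML file drives every stage.

An empty file is a valid configuration — every field has a documented
default, so ``simulate`` followed by ``run-all`` works with no hand-written
config.  Unknown keys and out-of-range values are rejected with the
offending key named.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .indices import IndexConfig
from .synthetic import GeneratorConfig

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    alpha: float = 0.10
    seed: int = 0
    climate_path: str | None = None
    out_dir: str | None = None
    windows: tuple[tuple[int, int], ...] | None = None  # None -> the nine defaults
    index: IndexConfig = field(default_factory=IndexConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha: must lie in (0, 1), got {self.alpha}")
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigurationError(f"log_level: unknown level {self.log_level!r}")

    def to_dict(self) -> dict:
        d = {
            "alpha": self.alpha,
            "seed": self.seed,
            "climate_path": self.climate_path,
            "out_dir": self.out_dir,
            "windows": None if self.windows is None else [list(w) for w in self.windows],
            "index": dataclasses.asdict(self.index),
            "generator": _generator_dict(self.generator),
            "log_level": self.log_level,
        }
        return d


def _generator_dict(g: GeneratorConfig) -> dict:
    d = dataclasses.asdict(g)
    d["wet_prob_by_month"] = list(d["wet_prob_by_month"])
    for k in ("t_trend", "p_trend"):
        v = d[k]
        d[k] = v.tolist() if hasattr(v, "tolist") and getattr(v, "ndim", 0) else float(v)
    return d


def _tupled(value, depth: int):
    if depth == 0 or not isinstance(value, (list, tuple)):
        return value
    return tuple(_tupled(v, depth - 1) for v in value)


_INDEX_TUPLE_FIELDS = {
    "season_start": 1, "season_end": 1,
    "cold_window": 2, "spring_window": 2, "growth_window": 2, "rot_window": 2,
}


def _build(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"{section}: unknown key(s) {sorted(unknown)}; known keys are {sorted(known)}"
        )
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigurationError(f"{section}: {exc}") from exc


def from_dict(data: dict | None) -> PipelineConfig:
    data = dict(data or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)}; known keys are {sorted(known)}"
        )
    index_data = dict(data.pop("index", {}) or {})
    for k, depth in _INDEX_TUPLE_FIELDS.items():
        if k in index_data:
            index_data[k] = _tupled(index_data[k], depth)
    gen_data = dict(data.pop("generator", {}) or {})
    if "wet_prob_by_month" in gen_data:
        gen_data["wet_prob_by_month"] = tuple(gen_data["wet_prob_by_month"])
    windows = data.pop("windows", None)
    if windows is not None:
        windows = tuple(_tupled(w, 1) for w in windows)
    index = _build(IndexConfig, index_data, "index")
    generator = _build(GeneratorConfig, gen_data, "generator")
    generator.validate()
    return _build(
        PipelineConfig,
        {**data, "index": index, "generator": generator, "windows": windows},
        "config",
    )


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; empty file means all defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    """Stable sha256 of the canonicalised config, for provenance records."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
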