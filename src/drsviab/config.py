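"""Run configuration: validated, fully-seeded settings for the pipeline.

The configuration is a plain YAML mapping; unknown keys are rejected by
name, every omitted key falls back to the study defaults (which reproduce
the published experiment scale), and the seed is mandatory in the sense
that no stage ever draws entropy outside ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .classify import ALL_FAMILIES
from .colecole import ColeColeParams
from .simulate import (
    DEFAULT_PHASE_TOTALS,
    ExperimentDesign,
    NoiseModel,
    build_state_library,
)
from .spectra import DEFAULT_F_MAX, DEFAULT_F_MIN, DEFAULT_N_POINTS

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass(frozen=True)
class GridConfig:
    f_min: float = DEFAULT_F_MIN
    f_max: float = DEFAULT_F_MAX
    n_points: int = DEFAULT_N_POINTS

    def __post_init__(self):
        if self.f_min >= self.f_max:
            raise ConfigError("grid: f_min must be below f_max")
        if self.n_points < 2:
            raise ConfigError("grid: n_points must be at least 2")


@dataclass(frozen=True)
class ClassifyConfig:
    families: tuple[str, ...] = ("linear_baseline",)
    bands: tuple[str, ...] = ("whole", "selected")
    k_outer: int = 5
    k_inner: int = 5
    grid_subsample: int = 8
    max_epochs: int = 100
    patience: int = 10
    group_aware: bool = False

    def __post_init__(self):
        for f in self.families:
            if f not in ALL_FAMILIES:
                raise ConfigError(f"classify.families: unknown family {f!r}")
        for b in self.bands:
            if b not in ("whole", "selected"):
                raise ConfigError(f"classify.bands: unknown band {b!r}")


@dataclass(frozen=True)
class ExplainConfig:
    n_records: int = 20
    n_background: int = 50
    n_permutations: int = 128
    use_relative_change: bool = True


@dataclass(frozen=True)
class StagesConfig:
    simulate: bool = True
    fit: bool = True
    classify: bool = True
    explain: bool = True


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "drsviab_out"
    grid: GridConfig = field(default_factory=GridConfig)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    noise: NoiseModel = field(default_factory=NoiseModel)
    library_overrides: dict = field(default_factory=dict)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    explain: ExplainConfig = field(default_factory=ExplainConfig)
    stages: StagesConfig = field(default_factory=StagesConfig)

    def state_library(self):
        overrides = {}
        base = build_state_library()
        for label, fields in self.library_overrides.items():
            if label not in base.entries:
                raise ConfigError(f"library_overrides: unknown condition {label!r}")
            try:
                overrides[label] = base[label].replace(**fields)
            except (TypeError, ValueError) as e:
                raise ConfigError(f"library_overrides[{label!r}]: {e}") from e
        return build_state_library(overrides)


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under {path!r}")
    kwargs = {}
    for f in dc_fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name in ("families", "bands") and isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid value under {path!r}: {e}") from e


_SECTIONS = {
    "grid": GridConfig,
    "noise": NoiseModel,
    "classify": ClassifyConfig,
    "explain": ExplainConfig,
    "stages": StagesConfig,
}


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; empty/missing content means defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config must be a YAML mapping")
        data = loaded
    if overrides:
        data = {**data, **{k: v for k, v in overrides.items() if v is not None}}

    top_allowed = {f.name for f in dc_fields(RunConfig)}
    unknown = set(data) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    kwargs: dict = {}
    for key in ("seed", "out_dir", "library_overrides"):
        if key in data:
            kwargs[key] = data[key]
    for key, cls in _SECTIONS.items():
        if key in data:
            if not isinstance(data[key], dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build(cls, data[key], key)
    if "design" in data:
        d = dict(data["design"])
        if "phase_totals" in d:
            pt = dict(DEFAULT_PHASE_TOTALS)
            pt.update(d["phase_totals"])
            d["phase_totals"] = pt
        kwargs["design"] = _build(ExperimentDesign, d, "design")

    cfg = _build(RunConfig, {**{k: data[k] for k in data if k in top_allowed and k not in kwargs}, **kwargs}, "<root>")
    cfg.state_library()  # validate overrides eagerly
    return cfg
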