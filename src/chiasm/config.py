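"""Run configuration: YAML/JSON parsing with a strict schema.

A run configuration selects a named grid preset (or spells out an explicit
grid), optionally overrides model/task constants, objective weights, the
repetition count and the base seed, and names an output directory.  Unknown
keys anywhere in the document are rejected with their full key path, so typos
fail loudly instead of silently running the defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .network import ModelParams
from .objective import ObjectiveWeights
from .scan import GridSpec, PRESET_NAMES, grid_preset
from .task import TaskParams

__all__ = ["RunConfig", "load_config", "build_grid"]


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings (defaults reproduce the baseline constants)."""

    preset: Optional[str] = None
    grid: Optional[dict] = None
    base_seed: int = 0
    repetitions: Optional[int] = None
    output_dir: str = "results"
    model: ModelParams = field(default_factory=ModelParams)
    task: TaskParams = field(default_factory=TaskParams)
    # None means "not overridden": grid presets keep their own weight preset
    objective: Optional[ObjectiveWeights] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_GRID_KEYS = {"d_long", "sigma", "i_inhib", "theta", "dims"}


def _merge_dataclass(cls, defaults, overrides: dict, path: str):
    """Replace fields of a frozen dataclass from a dict, strictly."""
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        key = sorted(unknown)[0]
        raise ValueError(f"unknown configuration key {path}.{key}")
    try:
        return dataclasses.replace(defaults, **overrides)
    except (TypeError, ValueError) as err:
        raise ValueError(f"invalid value under {path}: {err}") from err


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration file.

    An empty file yields the pure defaults.  Objective weights accept either
    explicit ``lambda_*`` keys or ``{"preset": <name>}``.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    known = {"preset", "grid", "base_seed", "repetitions", "output_dir",
             "model", "task", "objective"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration key {sorted(unknown)[0]}")
    cfg = RunConfig()
    model = _merge_dataclass(ModelParams, cfg.model, raw.get("model", {}), "model")
    task = _merge_dataclass(TaskParams, cfg.task, raw.get("task", {}), "task")
    objective: Optional[ObjectiveWeights] = None
    if "objective" in raw:
        obj_raw = dict(raw["objective"])
        base = ObjectiveWeights()
        if "preset" in obj_raw:
            base = ObjectiveWeights.preset(obj_raw.pop("preset"))
        objective = _merge_dataclass(ObjectiveWeights, base, obj_raw,
                                     "objective")
    preset = raw.get("preset")
    if preset is not None and preset not in PRESET_NAMES:
        raise ValueError(f"unknown grid preset under preset: {preset!r}")
    grid = raw.get("grid")
    if grid is not None:
        if not isinstance(grid, dict):
            raise ValueError("grid must be a mapping")
        unknown = set(grid) - _GRID_KEYS
        if unknown:
            raise ValueError(f"unknown configuration key grid.{sorted(unknown)[0]}")
    base_seed = raw.get("base_seed", 0)
    if not isinstance(base_seed, int) or base_seed < 0:
        raise ValueError("base_seed must be a nonnegative integer")
    reps = raw.get("repetitions")
    if reps is not None and (not isinstance(reps, int) or reps < 1):
        raise ValueError("repetitions must be a positive integer")
    return RunConfig(
        preset=preset,
        grid=grid,
        base_seed=base_seed,
        repetitions=reps,
        output_dir=str(raw.get("output_dir", cfg.output_dir)),
        model=model,
        task=task,
        objective=objective,
    )


def build_grid(cfg: RunConfig, preset: Optional[str] = None) -> GridSpec:
    """Materialize the GridSpec a configuration describes.

    ``preset`` (e.g. from the command line) takes precedence over the
    configured one; an explicit ``grid:`` block overrides the preset's axes.
    """
    name = preset or cfg.preset
    if name is not None:
        g = grid_preset(name, base_seed=cfg.base_seed,
                        repetitions=cfg.repetitions)
        g = dataclasses.replace(g, model=cfg.model)
        if cfg.objective is not None:
            g = dataclasses.replace(g, weights=cfg.objective)
        # model/objective overrides apply on top of the preset; the preset's
        # task (drive mode, dims) is part of its definition and is kept.
        if cfg.grid:
            g = dataclasses.replace(
                g,
                d_long_values=tuple(cfg.grid.get("d_long", g.d_long_values)),
                sigma_values=tuple(cfg.grid.get("sigma", g.sigma_values)),
                i_inhib_values=tuple(cfg.grid.get("i_inhib", g.i_inhib_values)),
                theta_values=tuple(cfg.grid.get("theta", g.theta_values)),
                dims=cfg.grid.get("dims", g.dims),
            )
        return g
    if not cfg.grid:
        raise ValueError("configuration names neither a preset nor a grid")
    missing = {"d_long", "sigma", "i_inhib", "theta"} - set(cfg.grid)
    if missing:
        raise ValueError(f"grid is missing axis {sorted(missing)[0]}")
    return GridSpec(
        d_long_values=tuple(cfg.grid["d_long"]),
        sigma_values=tuple(cfg.grid["sigma"]),
        i_inhib_values=tuple(cfg.grid["i_inhib"]),
        theta_values=tuple(cfg.grid["theta"]),
        dims=cfg.grid.get("dims", cfg.task.dims),
        repetitions=cfg.repetitions or 10,
        weights=cfg.objective if cfg.objective is not None else ObjectiveWeights(),
        base_seed=cfg.base_seed,
        name="custom",
        model=cfg.model,
        task=cfg.task,
    )


def write_provenance(directory, record: dict) -> None:
    """Write the machine-readable provenance record of an output directory."""
    import numpy
    import pandas
    import scipy

    from . import __version__

    record = dict(record)
    record["versions"] = {
        "chiasm": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj: Any):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")
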