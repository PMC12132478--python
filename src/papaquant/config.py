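"""Run configuration: validated, serializable, reproducible from (config, seed).

The YAML/JSON layout mirrors the parameter dataclasses.  Unknown keys are
rejected with the offending path named, so typos in a config file fail loudly
instead of silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from ._validation import ValidationError
from .segmentation import QCParams
from .synthetic_data import (
    FieldLayout,
    IlluminationSchedule,
    MotionParams,
    PhotophysicsParams,
    grid_layout,
)


@dataclass(frozen=True)
class BootstrapParams:
    n_boot_proximity: int = 100
    n_boot_scatter: int = 500
    percentiles: tuple[float, float] = (2.5, 97.5)


@dataclass(frozen=True)
class MobilityParams:
    grid_points: int = 101
    d_min: float = 0.01
    d_max: float = 100.0
    slow_threshold: float = 0.1
    max_iter: int = 1000
    tol: float = 1e-8


@dataclass(frozen=True)
class FrapParams:
    n_movies: int = 5
    n_frames: int = 200
    bleach_frame: int = 16
    frame_interval: float = 0.15
    mobile_fraction: float = 0.6
    tau: float = 5.0
    depth: float = 0.7
    spot_radius: float = 12.0


@dataclass(frozen=True)
class SimulationParams:
    n_nuclei: int = 20
    interacting_enrichment: float | None = None  # calibrate p_near to this if set


@dataclass(frozen=True)
class RunConfig:
    schedule: IlluminationSchedule = field(default_factory=IlluminationSchedule)
    photophysics: PhotophysicsParams = field(default_factory=PhotophysicsParams)
    motion: MotionParams = field(default_factory=MotionParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    qc: QCParams = field(default_factory=QCParams)
    bootstrap: BootstrapParams = field(default_factory=BootstrapParams)
    mobility: MobilityParams = field(default_factory=MobilityParams)
    frap: FrapParams = field(default_factory=FrapParams)
    seed: int = 0

    def layout(self) -> FieldLayout:
        return grid_layout(n_nuclei=self.simulation.n_nuclei)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _jsonable(d)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


_SECTION_TYPES = {
    "schedule": IlluminationSchedule,
    "photophysics": PhotophysicsParams,
    "motion": MotionParams,
    "simulation": SimulationParams,
    "qc": QCParams,
    "bootstrap": BootstrapParams,
    "mobility": MobilityParams,
    "frap": FrapParams,
}

_TUPLE_FIELDS = {"percentiles", "count_bounds", "exclude_edges"}


def _build_section(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValidationError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(data) - (set(_SECTION_TYPES) | {"seed"})
    if unknown:
        raise ValidationError(f"config: unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _build_section(cls, data[name], name)
    if "seed" in data:
        if not isinstance(data["seed"], int):
            raise ValidationError("config: seed must be an integer")
        kwargs["seed"] = data["seed"]
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except Exception as exc:
        raise ValidationError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        data = {}
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
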