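"""Pipeline configuration: YAML loading with strict validation.

A config file selects the synthetic condition, geometry, segmentation and
cascade parameters, the screen composition and the master seed. Unknown
keys are rejected by name so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .screen import CascadeParams
from .segmentation import SegParams
from .synthetic import CONDITIONS, ConditionSpec, FieldGeometry

__all__ = ["PipelineConfig", "load_config", "config_hash"]

_READOUTS = ("count", "intensity")
_TIERS = ("tabular", "image")


@dataclass
class LibrarySpec:
    """Composition of the synthetic compound library."""

    n_true_hit: int = 20
    n_disruptor: int = 20
    n_toxic: int = 20
    n_inactive: int = 308

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigurationError(f"library.{f.name} must be >= 0")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring)."""

    seed: int = 0
    tier: str = "tabular"
    condition: str = "CLM+NU7441"
    readout: str = "count"
    n_fields: int = 2
    n_controls: int = 16
    cells_per_well: int = 3000
    condition_overrides: dict = field(default_factory=dict)
    geometry: FieldGeometry = field(default_factory=FieldGeometry)
    seg: SegParams = field(default_factory=SegParams)
    cascade: CascadeParams = field(default_factory=CascadeParams)
    library: LibrarySpec = field(default_factory=LibrarySpec)

    def __post_init__(self) -> None:
        if self.tier not in _TIERS:
            raise ConfigurationError(f"tier must be one of {_TIERS}, got {self.tier!r}")
        if self.readout not in _READOUTS:
            raise ConfigurationError(
                f"readout must be one of {_READOUTS}, got {self.readout!r}"
            )
        if self.condition not in CONDITIONS:
            raise ConfigurationError(
                f"condition must be one of {sorted(CONDITIONS)}, got {self.condition!r}"
            )

    def condition_spec(self) -> ConditionSpec:
        base = CONDITIONS[self.condition]
        if not self.condition_overrides:
            return base
        return dataclasses.replace(base, **self.condition_overrides)


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown config key {path}{sorted(unknown)[0]!r}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid config section {path or 'top level'}: {exc}") from None


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; errors name offending keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    sections = {
        "geometry": FieldGeometry,
        "seg": SegParams,
        "cascade": CascadeParams,
        "library": LibrarySpec,
    }
    parsed = dict(raw)
    for key, cls in sections.items():
        sub = parsed.pop(key, None)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            raise ConfigurationError(f"config section {key!r} must be a mapping")
        if key == "geometry" and "shape" in sub:
            sub = {**sub, "shape": tuple(sub["shape"])}
        if key == "cascade" and "doses" in sub:
            sub = {**sub, "doses": tuple(sub["doses"])}
        parsed[key] = _build(cls, sub, f"{key}.")
    overrides = parsed.get("condition_overrides")
    if overrides is not None:
        bad = set(overrides) - {f.name for f in dataclasses.fields(ConditionSpec)}
        if bad:
            raise ConfigurationError(f"unknown condition override {sorted(bad)[0]!r}")
    return _build(PipelineConfig, parsed, "")


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of a config, stamped into every output artifact."""
    canon = yaml.safe_dump(_to_plain(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj
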