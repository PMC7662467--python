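"""YAML-backed run configuration bundling every stage's parameters.

Unknown keys are rejected so that a typo in a config file fails loudly
instead of silently using a default.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .core_io import EventKind
from .features import WindowScheme
from .models import EventModelConfig, SleepWakeConfig
from .simulate import SimConfig

_TUPLE_FIELDS = {"strides", "fc_nodes", "desat_depth_pct", "breath_hz",
                 "wake_bout_len_s"}


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    scheme: WindowScheme = dataclasses.field(default_factory=WindowScheme)
    event_model: EventModelConfig = dataclasses.field(
        default_factory=EventModelConfig)
    sleepwake: SleepWakeConfig = dataclasses.field(default_factory=SleepWakeConfig)
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)

    def with_seed(self, seed: int | None) -> "RunConfig":
        """Propagate one seed into every stage (CLI flag > YAML > default)."""
        if seed is None:
            return self
        return RunConfig(
            seed=seed,
            scheme=self.scheme,
            event_model=dataclasses.replace(self.event_model, seed=seed),
            sleepwake=dataclasses.replace(self.sleepwake, seed=seed),
            sim=dataclasses.replace(self.sim, seed=seed),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["event_rate_per_h"] = {
            k.value: v for k, v in self.sim.event_rate_per_h.items()}
        return d

    def digest(self) -> str:
        """Stable short hash of the full configuration (for run logs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config "
                         f"section {path!r}; allowed: {sorted(names)}")
    coerced = {}
    for k, v in data.items():
        if k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        if k == "event_rate_per_h":
            v = {EventKind(kk.upper()): float(vv) for kk, vv in v.items()}
        coerced[k] = v
    return cls(**coerced)


_SECTIONS = {"scheme": WindowScheme, "event_model": EventModelConfig,
             "sleepwake": SleepWakeConfig, "sim": SimConfig}


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s) {sorted(unknown)}; "
                         f"allowed: {sorted(set(_SECTIONS) | {'seed'})}")
    kwargs = {"seed": int(data.get("seed", 0))}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build(cls, data.get(name, {}) or {}, name)
    return RunConfig(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text())
    return config_from_dict(data or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
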