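"""Run configuration: strict YAML-backed settings shared by the CLI.

Unknown keys are rejected (fail fast on typos) and a config round-trips
through serialisation losslessly, so the provenance hash recorded in
output headers identifies the exact settings of a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import ColumnMap, TrimPolicy
from .synthetic_data import GeneratorConfig

__all__ = ["RunConfig", "UnknownConfigKeyError", "config_hash"]


class UnknownConfigKeyError(ValueError):
    """A configuration mapping contained a key no setting matches."""


def _from_mapping(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise UnknownConfigKeyError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in mapping:
            continue
        value = mapping[f.name]
        if dataclasses.is_dataclass(f.type) and isinstance(value, dict):
            value = _from_mapping(f.type, value)
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs beyond its input files."""

    columns: ColumnMap = ColumnMap()
    trim: TrimPolicy = TrimPolicy()
    generator: GeneratorConfig = GeneratorConfig()
    model: str = "M4"
    age_centering: float = 0.0
    cpi_reference_year: int = 2006
    holdout_year: int = 2006
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        sections = dict(mapping)
        kwargs = {}
        for name, sub_cls in (("columns", ColumnMap), ("trim", TrimPolicy),
                              ("generator", GeneratorConfig)):
            if name in sections:
                sub = dict(sections.pop(name))
                for key in ("units_per_minor", "years", "age_range_female",
                            "age_range_male"):
                    if key in sub and isinstance(sub[key], list):
                        sub[key] = tuple(sub[key])
                kwargs[name] = _from_mapping(sub_cls, sub)
        top = _from_mapping(cls, sections)
        return dataclasses.replace(top, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh) or {}
        return cls.from_mapping(mapping)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def config_hash(config: RunConfig) -> str:
    """Short stable digest of a run configuration, for provenance headers."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
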