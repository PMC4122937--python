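"""Run configuration: every stage's tunables in one serialisable object."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fragmentation import FragsiteParams
from .mapper import MapperParams
from .simulate import SimParams
from .telomere import TelomereSpec
from .terminator import ExtensionParams, MergeParams

__all__ = ["RunConfig"]

_SECTIONS = {
    "telomere": TelomereSpec,
    "sim": SimParams,
    "mapper": MapperParams,
    "extension": ExtensionParams,
    "merge": MergeParams,
    "fragsites": FragsiteParams,
}


@dataclass
class RunConfig:
    """All tunables of every pipeline stage, with their defaults.

    Serialises to YAML and back; every CLI run logs the fully resolved
    config in its manifest so thresholds are never implicit.
    """

    telomere: TelomereSpec = field(default_factory=TelomereSpec)
    sim: SimParams = field(default_factory=SimParams)
    mapper: MapperParams = field(default_factory=MapperParams)
    extension: ExtensionParams = field(default_factory=ExtensionParams)
    merge: MergeParams = field(default_factory=MergeParams)
    fragsites: FragsiteParams = field(default_factory=FragsiteParams)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        for name, klass in _SECTIONS.items():
            section = data.get(name, {})
            unknown = set(section) - {f.name for f in dataclasses.fields(klass)}
            if unknown:
                raise ValueError(f"unknown {name} option(s): {sorted(unknown)}")
            kwargs[name] = klass(**section)
        kwargs["seed"] = int(data.get("seed", 0))
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "RunConfig":
        out = dataclasses.replace(self, sim=dataclasses.replace(self.sim,
                                                                seed=seed))
        out.seed = seed
        return out
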