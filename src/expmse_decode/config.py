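"""Run configuration: validated, hashable, YAML round-trippable."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigError
from .simulate import (EffectSpec, REGION_GROUPS, SimulationConfig,
                       default_effects)


def _from_dict(cls, data: dict):
    """Build a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{cls.__name__}: expected a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class SimulationSection:
    n_subjects: int = 3
    n_regions: int = 6
    region_labels: tuple[str, ...] | None = (
        "lateraloccipital-lh", "pericalcarine-lh",
        "precentral-lh", "postcentral-lh",
        "superiorfrontal-lh", "rostralmiddlefrontal-lh",
    )
    fs: float = 400.0
    n_sessions: int = 3
    trials_per_task: int = 4
    tasks: tuple[str, ...] = ("VP", "VI", "ME", "MI")
    rest_s: float = 6.0
    task_s: float = 6.0
    noise_exponent: float = 1.0
    effect_jitter_sd: float = 0.15
    #: "default" or a list of effect mappings
    effects: str | tuple = "default"

    def to_simulation_config(self, master_seed: int) -> SimulationConfig:
        return SimulationConfig(
            n_subjects=self.n_subjects, n_regions=self.n_regions,
            fs=self.fs, n_sessions=self.n_sessions,
            trials_per_task=self.trials_per_task, tasks=tuple(self.tasks),
            rest_s=self.rest_s, task_s=self.task_s,
            noise_exponent=self.noise_exponent, master_seed=master_seed,
            region_labels=tuple(self.region_labels)
            if self.region_labels else None,
            effect_jitter_sd=self.effect_jitter_sd,
        )

    def to_effects(self, sim: SimulationConfig) -> list[EffectSpec]:
        if self.effects == "default":
            return default_effects(sim)
        out = []
        for e in self.effects:
            e = dict(e)
            regions = e.pop("regions", None)
            group = e.pop("group", None)
            if regions is None:
                if group is None:
                    raise ConfigError(
                        "effect needs 'regions' or a 'group' name")
                regions = tuple(r for r in REGION_GROUPS[group]
                                if r in sim.region_labels)
            out.append(EffectSpec(regions=tuple(regions), **e))
        return out


@dataclass(frozen=True)
class DecompositionSection:
    noise_sd_ratio: float = 0.2
    n_ensembles: int = 8
    max_imf: int = 10


@dataclass(frozen=True)
class EntropySection:
    m: int = 2
    r: float = 0.2
    cap: int = 30_000
    bin_s: float = 0.64


@dataclass(frozen=True)
class FeaturesSection:
    decoded_tasks: tuple[str, ...] = ("VP", "VI", "ME", "MI")
    crop_k: int = 4
    raw_window: int = 400
    raw_step: int = 6
    kinds: tuple[str, ...] = ("expmse",)


@dataclass(frozen=True)
class DecoderSection:
    design: str = "intra"
    kind: str = "expmse"
    two_class: bool = False
    filters: tuple[int, int] = (8, 16)
    learning_rate: float = 1e-3
    batch_size: int = 64
    patience: int = 5
    max_epochs: int = 40
    permute_labels: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration with a stable content hash."""

    seed: int = 0
    simulation: SimulationSection = field(default_factory=SimulationSection)
    decomposition: DecompositionSection = field(
        default_factory=DecompositionSection)
    entropy: EntropySection = field(default_factory=EntropySection)
    features: FeaturesSection = field(default_factory=FeaturesSection)
    decoder: DecoderSection = field(default_factory=DecoderSection)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sections = {
            "simulation": SimulationSection,
            "decomposition": DecompositionSection,
            "entropy": EntropySection,
            "features": FeaturesSection,
            "decoder": DecoderSection,
        }
        known = set(sections) | {"seed"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"RunConfig: unknown keys {sorted(unknown)}")
        kwargs = {"seed": data.get("seed", 0)}
        for name, section_cls in sections.items():
            if name in data:
                kwargs[name] = _from_dict(section_cls, data[name])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.canonical_json()), fh,
                           sort_keys=True)

    def canonical_json(self) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj
        return json.dumps(clean(self.to_dict()), sort_keys=True)

    def config_hash(self, *parts: str) -> str:
        """Hash of the whole config, or of selected top-level sections."""
        data = json.loads(self.canonical_json())
        if parts:
            data = {k: data[k] for k in ("seed",) + parts}
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


__all__ = [
    "SimulationSection", "DecompositionSection", "EntropySection",
    "FeaturesSection", "DecoderSection", "RunConfig",
]
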