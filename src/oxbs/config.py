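"""YAML configuration for the simulator / pipeline."""

from __future__ import annotations

from dataclasses import fields

import yaml

from .chemistry import ChemistryParams
from .pipeline import ExperimentConfig
from .sim.genome import GenomeConfig
from .sim.truth import HippocampusProfile

__all__ = ["load_config", "dump_config"]


def _build(cls, mapping: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("cgi_length_range", "repeat_length_range", "ages"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path=None, text: str | None = None) -> ExperimentConfig:
    """Experiment configuration from YAML (missing sections use defaults)."""
    if text is None:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text) or {}
    return ExperimentConfig(
        genome=_build(GenomeConfig, raw.get("genome", {})),
        profile=_build(HippocampusProfile, raw.get("profile", {})),
        chemistry=_build(ChemistryParams, raw.get("chemistry", {})),
        coverage=float(raw.get("coverage", 10.0)),
        n_per_cell=int(raw.get("n_per_cell", 3)),
        ages=tuple(raw.get("ages", ("young", "old"))),
    )


def dump_config(config: ExperimentConfig) -> str:
    def as_dict(obj):
        return {f.name: getattr(obj, f.name) for f in fields(obj)}

    raw = {
        "genome": as_dict(config.genome),
        "profile": as_dict(config.profile),
        "chemistry": as_dict(config.chemistry),
        "coverage": config.coverage,
        "n_per_cell": config.n_per_cell,
        "ages": list(config.ages),
    }
    for key in ("cgi_length_range", "repeat_length_range"):
        raw["genome"][key] = list(raw["genome"][key])
    return yaml.safe_dump(raw, sort_keys=False)
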