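"""Pipeline configuration: one structured file drives the whole run.

Thresholds default to the values used throughout the analysis: calling floor
depth 10 and alternate fraction 0.1, candidate threshold ΔSNP-index > 0.38,
and a candidate region centred on the simulated causal locus whose width is
chosen so it holds about the same number of sites as the published physical
interval does at real transcriptome density (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .markers import RegionFilter
from .simulate import PARENT_B, SimulationConfig

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything run-all needs: simulation layout, thresholds, region, seed."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_depth: int = 10
    min_alt_fraction: float = 0.1
    min_delta: float = 0.38
    region: RegionFilter | None = None  # None -> causal locus +/- region_half_width
    region_half_width: int = 5_200_000
    donor_parent: str = PARENT_B
    seed: int = 0
    n_mapping_individuals: int = 788
    max_markers: int = 4
    outdir: str = "wheatbsa-run"
    figures: bool = False

    def validate(self) -> None:
        if self.min_depth < 1:
            raise ConfigError("min_depth must be >= 1")
        if not 0 <= self.min_alt_fraction <= 1:
            raise ConfigError("min_alt_fraction must be in [0, 1]")
        if not -1 <= self.min_delta <= 1:
            raise ConfigError("min_delta must be in [-1, 1]")
        if self.n_mapping_individuals < 2:
            raise ConfigError("n_mapping_individuals must be >= 2")
        self.simulation.genome.validate()
        self.simulation.pedigree.validate()

    def resolved_region(self) -> RegionFilter:
        if self.region is not None:
            return self.region
        chrom = self.simulation.genome.causal_chrom
        pos = self.simulation.genome.causal_pos
        length = dict(self.simulation.genome.chromosomes)[chrom]
        return RegionFilter(
            chrom, max(1, pos - self.region_half_width), min(length, pos + self.region_half_width)
        )

    # -- serialization --------------------------------------------------

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(_to_plain(self), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            cfg = _from_plain(cls, data)
        except (TypeError, KeyError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc
        cfg.validate()
        return cfg


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _from_plain(cls, data):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        typ = f.type if isinstance(f.type, type) else None
        if dataclasses.is_dataclass(f.default_factory() if f.default_factory is not dataclasses.MISSING else None):
            inner_cls = type(f.default_factory())
            kwargs[f.name] = _from_plain(inner_cls, value or {})
        elif f.name == "region" and value is not None:
            kwargs[f.name] = RegionFilter(**value)
        elif f.name == "chromosomes" and value is not None:
            kwargs[f.name] = tuple((c, int(l)) for c, l in value)
        else:
            kwargs[f.name] = value
    return cls(**kwargs)
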