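"""Declarative pipeline configuration with YAML round-trip.

One config object carries every tunable of the workflow; the defaults
are the validated Orbitrap settings (5000-count intensity threshold in
at least 3 scans, 2.5 ppm m/z tolerance, ±20 % isotopologue-abundance
error, ±15-scan co-elution window, 0.5 pairing correlation, ±10-scan
grouping window, 0.85 grouping correlation, ±10 ppm cluster split and
bracketing tolerance, ±0.15 min bracketing Rt tolerance).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bracketing import BracketParams
from .feature_extract import FeatureParams
from .isotope_math import EnrichmentModel
from .pair_scan import PairParams
from .simulate import SimConfig

__all__ = ["PipelineConfig"]


def _tupled(cls, data: dict):
    """Rebuild a (frozen) dataclass from a dict, restoring tuple fields."""
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    pair: PairParams = field(default_factory=PairParams)
    feature: FeatureParams = field(default_factory=FeatureParams)
    bracket: BracketParams = field(default_factory=BracketParams)
    sim: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        pair_d = dict(data.get("pair", {}))
        enr = pair_d.pop("enrichment", None)
        pair = _tupled(PairParams, pair_d)
        if enr is not None:
            pair = dataclasses.replace(pair, enrichment=EnrichmentModel(**enr))
        sim_d = dict(data.get("sim", {}))
        sim_enr = sim_d.pop("enrichment", None)
        sim = _tupled(SimConfig, sim_d)
        if sim_enr is not None:
            sim = dataclasses.replace(sim, enrichment=EnrichmentModel(**sim_enr))
        return cls(
            pair=pair,
            feature=_tupled(FeatureParams, data.get("feature", {})),
            bracket=_tupled(BracketParams, data.get("bracket", {})),
            sim=sim,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
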