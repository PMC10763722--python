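"""Pipeline configuration: YAML round-trip and the end-to-end report runner.

A single master seed in the config drives every stage; child seeds are
derived deterministically, so rerunning with the same config reproduces
the report bit-for-bit (modulo the timestamp field).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .geometry import GenotypeParams, genotype_defaults
from .profiler import AssignConfig, FitConfig
from .simulate import GelSimParams, StedSimParams


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of the simulate → profile → stats pipeline."""

    geometry: dict[str, GenotypeParams] = field(
        default_factory=lambda: {
            label: genotype_defaults(label) for label in ("TTNTV_NEG", "TTNTV_POS", "CONTROL")
        }
    )
    genotypes: tuple[str, ...] = ("TTNTV_NEG", "TTNTV_POS")
    sl_um_values: tuple[float, ...] = (1.8, 2.0, 2.2, 2.4, 2.6)
    n_profiles_per_sl: int = 10
    simulation: StedSimParams = field(default_factory=StedSimParams)
    gel: GelSimParams = field(default_factory=GelSimParams)
    fit: FitConfig = field(default_factory=FitConfig)
    assign: AssignConfig = field(default_factory=AssignConfig)
    sl_range_um: tuple[float, float] = (1.8, 2.6)
    seed: int = 0
    output_dir: str = "titinsted-report"

    # -- YAML round-trip ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = {k: dataclasses.asdict(v) for k, v in self.geometry.items()}
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        if "geometry" in kwargs:
            kwargs["geometry"] = {
                k: GenotypeParams(**v) for k, v in kwargs["geometry"].items()
            }
        for key, typ in (("simulation", StedSimParams), ("gel", GelSimParams),
                         ("fit", FitConfig), ("assign", AssignConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**_lists_to_tuples_for(typ, kwargs[key]))
        for key in ("genotypes", "sl_um_values", "sl_range_um"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _lists_to_tuples_for(typ, d: dict) -> dict:
    """Coerce list-valued fields back to tuples per the dataclass annotations."""
    out = dict(d)
    for f in dataclasses.fields(typ):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = _coerce(out[f.name])
    return out


def _coerce(value):
    return tuple(_coerce(v) if isinstance(v, list) else v for v in value)
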